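"""Ordered hallmark-motif filter for functional A1A aspartic peptidases.

Pepsin-like (A1A) aspartic peptidases carry two catalytic D[TS]G motifs on
opposing lobes, each followed by a hydrophobic XXG, plus a conserved
tyrosine in the flap region. A homolog is called functional when the five
signatures D[TS]G, Y, XXG, D[TS]G, XXG (X any of A, F, I, L, M, V) occur in
this order along the sequence; a sequence missing any of them is treated as
a non-functional homolog.

The scan is greedy left-to-right: motif i+1 is sought strictly after the
end of motif i's earliest match. For this motif set greedy earliest
matching cannot produce a false negative relative to exhaustive ordered
search (checked against a brute-force oracle in the test suite rather than
assumed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .records import ProteinRecord, write_fasta

HYDROPHOBIC_X = "AFILMV"

#: The five ordered hallmark patterns.
MOTIF_PATTERNS: tuple[str, ...] = (
    r"D[TS]G", r"Y", rf"[{HYDROPHOBIC_X}][{HYDROPHOBIC_X}]G",
    r"D[TS]G", rf"[{HYDROPHOBIC_X}][{HYDROPHOBIC_X}]G",
)
_COMPILED = tuple(re.compile(p) for p in MOTIF_PATTERNS)


@dataclass(frozen=True)
class HallmarkResult:
    """Outcome of the ordered five-motif scan on one sequence.

    ``positions`` are 0-based (start, end) half-open spans of the matched
    motifs; add 1 to starts for 1-based reporting. On failure,
    ``failed_motif`` is the 1-based index of the first motif not found.
    """

    sequence_id: str
    passed: bool
    positions: tuple[tuple[int, int], ...]
    failed_motif: int | None

    def __post_init__(self) -> None:
        if self.passed:
            ends = [-1]
            for start, end in self.positions:
                if start < ends[-1]:
                    raise ValueError("hallmark positions must be ordered and non-overlapping")
                ends.append(end)


def scan_hallmarks(sequence: str, sequence_id: str = "") -> HallmarkResult:
    """Greedy ordered scan for the five A1A hallmarks."""
    seq = sequence.upper()
    positions: list[tuple[int, int]] = []
    cursor = 0
    for i, pattern in enumerate(_COMPILED, start=1):
        m = pattern.search(seq, cursor)
        if m is None:
            return HallmarkResult(sequence_id, False, tuple(positions), i)
        positions.append((m.start(), m.end()))
        cursor = m.end()
    return HallmarkResult(sequence_id, True, tuple(positions), None)


def filter_functional(records: list[ProteinRecord]
                      ) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame]:
    """Partition sequences into functional / non-functional homologs.

    Returns (functional, non_functional, report). The report carries one row
    per input with 1-based motif start positions and the failure reason.
    """
    functional, non_functional, rows = [], [], []
    for rec in records:
        res = scan_hallmarks(rec.sequence, rec.id)
        (functional if res.passed else non_functional).append(rec)
        rows.append({
            "id": rec.id,
            "passed": res.passed,
            "positions": ";".join(f"{s + 1}-{e}" for s, e in res.positions),
            "failed_motif": res.failed_motif if res.failed_motif is not None else "",
        })
    report = pd.DataFrame(rows, columns=["id", "passed", "positions", "failed_motif"])
    return functional, non_functional, report


def write_partition(functional: list[ProteinRecord], non_functional: list[ProteinRecord],
                    report: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(functional, out / "functional.fasta")
    write_fasta(non_functional, out / "non_functional.fasta")
    report.to_csv(out / "hallmark_report.tsv", sep="\t", index=False)
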