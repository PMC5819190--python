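"""Sequence record types shared across the mining and simulation modules."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: MEROPS-style family code: catalytic-type letter, family number, optional
#: subfamily letter (e.g. A01, S08, A01A).
FAMILY_CODE_RE = re.compile(r"^[ACGMNSTPU]\d+[A-Z]?$")

#: Header dialect of the synthetic reference library: ``>ID|FAM=A01|TYPE=A``.
REFERENCE_HEADER_RE = re.compile(r"^(?P<id>[^|\s]+)\|FAM=(?P<family>[^|\s]+)\|TYPE=(?P<type>[A-Z])")

CATALYTIC_TYPE_NAMES: dict[str, str] = {
    "A": "Aspartic",
    "C": "Cysteine",
    "G": "Glutamic",
    "M": "Metallo",
    "N": "Asparagine",
    "S": "Serine",
    "T": "Threonine",
    "P": "Mixed",
    "U": "Unknown",
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species and growth-temperature group."""

    id: str
    sequence: str
    species: str = ""
    group: str = ""


@dataclass(frozen=True)
class ReferenceEntry:
    """An annotated peptidase reference sequence.

    The catalytic-type letter always equals the leading letter of the family
    code for well-formed codes.
    """

    id: str
    family_code: str
    catalytic_letter: str
    sequence: str

    def __post_init__(self) -> None:
        if FAMILY_CODE_RE.match(self.family_code) and self.catalytic_letter != self.family_code[0]:
            raise ValueError(
                f"catalytic letter {self.catalytic_letter!r} does not match "
                f"family code {self.family_code!r}"
            )


@dataclass(frozen=True)
class PeptidaseAnnotation:
    """Best-hit assignment of a query to a reference peptidase family."""

    query_id: str
    family_code: str
    catalytic_type: str
    score: float
    identity: float  # percent over aligned columns, 0..100
    coverage: float  # aligned query columns / query length, 0..1
    reference_id: str = ""
    species: str = ""


@dataclass(frozen=True)
class NoCall:
    """Explicit non-assignment of a query, with the reason."""

    query_id: str
    reason: str


def validate_family_code(code: str) -> str:
    if not FAMILY_CODE_RE.match(code):
        raise ValueError(f"malformed peptidase family code: {code!r}")
    return code


def write_fasta(records: Iterable[ProteinRecord] | Iterable[ReferenceEntry], path: str | Path) -> None:
    """Write records to FASTA; reference entries use the annotated header dialect."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, ReferenceEntry):
            header = f"{rec.id}|FAM={rec.family_code}|TYPE={rec.catalytic_letter}"
        else:
            header = rec.id
        seqrecords.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def read_proteome_fasta(path: str | Path, species: str = "", group: str = "") -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), species=species, group=group)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def parse_reference_header(header: str, pattern: re.Pattern | None = None) -> tuple[str, str]:
    """Extract (id, family_code) from a reference FASTA header.

    ``pattern`` may override the default dialect with any regex exposing
    ``id`` and ``family`` named groups (e.g. for genuine MEROPS pepunit
    headers).
    """
    m = (pattern or REFERENCE_HEADER_RE).match(header)
    if m is None:
        raise ValueError(f"unparseable reference header: {header!r}")
    return m.group("id"), m.group("family")


def read_reference_fasta(path: str | Path, pattern: re.Pattern | None = None) -> list[ReferenceEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, family = parse_reference_header(rec.id, pattern)
        validate_family_code(family)
        entries.append(
            ReferenceEntry(
                id=rid,
                family_code=family,
                catalytic_letter=family[0],
                sequence=str(rec.seq),
            )
        )
    return entries


def iter_fasta(path: str | Path) -> Iterator[SeqRecord]:
    return SeqIO.parse(str(path), "fasta")
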