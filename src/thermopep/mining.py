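"""Best-hit peptidase classification against an annotated reference library.

A k-mer prescreen ranks reference candidates by the number of shared
distinct k-mers; the top candidates are rescored by exact local
Smith-Waterman alignment (BLOSUM62, affine gaps: a gap of length g costs
11 + g). The best scoring hit is emitted only if it passes the score,
identity and coverage thresholds, so every emitted annotation is a
defensible family call. Non-standard residues (B, J, O, U, X, Z) are scored
as neutral (0) against everything.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .matrix import CountMatrix
from .records import (
    CATALYTIC_TYPE_NAMES,
    NoCall,
    PeptidaseAnnotation,
    ProteinRecord,
    ReferenceEntry,
)

_EXTENDED_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBJOUXZ"
_NEUTRAL = set("BJOUXZ")


def _build_matrix() -> substitution_matrices.Array:
    blosum = substitution_matrices.load("BLOSUM62")
    m = substitution_matrices.Array(alphabet=_EXTENDED_ALPHABET, dims=2)
    for a in _EXTENDED_ALPHABET:
        for b in _EXTENDED_ALPHABET:
            if a in _NEUTRAL or b in _NEUTRAL:
                m[a, b] = 0.0
            else:
                m[a, b] = blosum[a, b]
    return m


_MATRIX = _build_matrix()


def make_aligner(gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    """Local aligner; gap costs in the BLAST convention (length-g gap = open + g·extend)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(query: str, subject: str,
                   aligner: Align.PairwiseAligner | None = None
                   ) -> tuple[float, float, float]:
    """Best local alignment of query vs subject.

    Returns (raw score, percent identity over aligned columns, query
    coverage fraction = aligned query columns / query length).
    """
    aligner = aligner or make_aligner()
    alignments = aligner.align(query.upper(), subject.upper())
    score = float(alignments.score)
    if score <= 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    q_blocks, s_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        aligned_cols += qe - qs
        matches += sum(a == b for a, b in zip(query[qs:qe].upper(), subject[ss:se].upper()))
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / len(query) if query else 0.0
    return score, identity, coverage


# ---------------------------------------------------------------------------
# k-mer prescreen

@dataclass
class KmerIndex:
    k: int
    postings: dict[str, list[int]]
    entries: list[ReferenceEntry]


def build_kmer_index(reference: list[ReferenceEntry], k: int = 4) -> KmerIndex:
    """Map every distinct k-mer of each reference entry to that entry."""
    if not reference:
        raise ValueError("cannot index an empty reference library")
    if not 3 <= k <= 6:
        raise ValueError("k must be between 3 and 6")
    postings: dict[str, list[int]] = defaultdict(list)
    for i, entry in enumerate(reference):
        seq = entry.sequence.upper()
        for kmer in {seq[j:j + k] for j in range(len(seq) - k + 1)}:
            postings[kmer].append(i)
    return KmerIndex(k=k, postings=dict(postings), entries=list(reference))


@dataclass
class MiningParams:
    """Thresholds of the classifier; all exposed, none claimed canonical."""

    k: int = 4
    min_shared_kmers: int = 8
    min_score: float = 60.0
    min_identity: float = 30.0
    min_coverage: float = 0.5
    max_candidates: int = 50
    gap_open: int = 11
    gap_extend: int = 1


def family_to_catalytic_type(family_code: str) -> str:
    """Catalytic-type name from the leading letter of a family code."""
    if not family_code:
        raise ValueError("empty family code")
    letter = family_code[0].upper()
    if letter not in CATALYTIC_TYPE_NAMES:
        raise ValueError(f"family code with unknown catalytic letter: {family_code!r}")
    return CATALYTIC_TYPE_NAMES[letter]


def classify_protein(query: ProteinRecord, index: KmerIndex,
                     params: MiningParams | None = None,
                     aligner: Align.PairwiseAligner | None = None
                     ) -> PeptidaseAnnotation | NoCall:
    """Assign a query to its best-hit reference family, or return a no-call."""
    params = params or MiningParams()
    seq = query.sequence.upper()
    kmers = {seq[j:j + index.k] for j in range(len(seq) - index.k + 1)
             if all(c in _EXTENDED_ALPHABET for c in seq[j:j + index.k])}
    if len(seq) < index.k or not kmers:
        return NoCall(query.id, "too short")

    shared = np.zeros(len(index.entries), dtype=int)
    for kmer in kmers:
        for i in index.postings.get(kmer, ()):
            shared[i] += 1
    candidates = np.nonzero(shared >= params.min_shared_kmers)[0]
    if candidates.size == 0:
        return NoCall(query.id, "no candidate passed the k-mer prescreen")
    # rank by shared k-mers desc, stable on reference order
    candidates = candidates[np.argsort(-shared[candidates], kind="stable")]
    candidates = candidates[:params.max_candidates]

    aligner = aligner or make_aligner(params.gap_open, params.gap_extend)
    best: tuple[float, float, str] | None = None  # (-score, -identity, ref id) min-key
    best_hit = None
    for i in candidates:
        entry = index.entries[i]
        score, identity, coverage = smith_waterman(seq, entry.sequence, aligner)
        key = (-score, -identity, entry.id)
        if best is None or key < best:
            best = key
            best_hit = (entry, score, identity, coverage)

    entry, score, identity, coverage = best_hit
    if score < params.min_score:
        return NoCall(query.id, f"best score {score:.1f} below threshold")
    if identity < params.min_identity:
        return NoCall(query.id, f"best identity {identity:.1f} below threshold")
    if coverage < params.min_coverage:
        return NoCall(query.id, f"best coverage {coverage:.2f} below threshold")
    return PeptidaseAnnotation(
        query_id=query.id,
        family_code=entry.family_code,
        catalytic_type=family_to_catalytic_type(entry.family_code),
        score=score,
        identity=identity,
        coverage=coverage,
        reference_id=entry.id,
        species=query.species,
    )


def classify_proteome(records: list[ProteinRecord], index: KmerIndex,
                      params: MiningParams | None = None
                      ) -> tuple[list[PeptidaseAnnotation], list[NoCall]]:
    params = params or MiningParams()
    aligner = make_aligner(params.gap_open, params.gap_extend)
    annotations, nocalls = [], []
    for rec in records:
        result = classify_protein(rec, index, params, aligner)
        (annotations if isinstance(result, PeptidaseAnnotation) else nocalls).append(result)
    return annotations, nocalls


def annotations_table(annotations: list[PeptidaseAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "query": a.query_id, "species": a.species, "family": a.family_code,
        "catalytic_type": a.catalytic_type, "score": a.score,
        "identity": a.identity, "coverage": a.coverage, "reference": a.reference_id,
    } for a in annotations])


def profile_species(annotations: list[PeptidaseAnnotation],
                    species_groups: dict[str, str],
                    level: str = "catalytic_type") -> CountMatrix:
    """Count annotated queries per species per category (census-style matrix).

    ``level`` is "catalytic_type" or "family"; every species in
    ``species_groups`` gets a row, all-zero when it has no annotations.
    """
    if level not in ("catalytic_type", "family"):
        raise ValueError("level must be 'catalytic_type' or 'family'")
    key = "catalytic_type" if level == "catalytic_type" else "family"
    cats: dict[str, dict[str, int]] = {sp: defaultdict(int) for sp in species_groups}
    for a in annotations:
        if a.species not in cats:
            raise ValueError(f"annotation for unknown species {a.species!r}")
        cats[a.species][getattr(a, "family_code" if key == "family" else key)] += 1
    all_cats = sorted({c for d in cats.values() for c in d})
    counts = pd.DataFrame(
        [[cats[sp].get(c, 0) for c in all_cats] for sp in species_groups],
        index=list(species_groups), columns=all_cats, dtype=int,
    )
    return CountMatrix(counts, pd.Series(species_groups))
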