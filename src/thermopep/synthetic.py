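"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream analyses
assume: proteomes as i.i.d. residue draws from a (possibly shifted)
background frequency vector with reference-derived peptidase homologs mixed
in, species-by-category count matrices as overdispersed gamma-Poisson
draws, protein structures as atom slabs with a known number of hollow
shells, and labeled positive/negative sets for the hallmark scan. All
generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .amino import STANDARD_AA, background_vector
from .matrix import CountMatrix
from .records import ProteinRecord, ReferenceEntry, validate_family_code
from .structure import StructureModel, radius_for_element


@dataclass
class ProteomeRegime:
    """Generative regime of one synthetic proteome.

    ``baseline_freqs`` is a 20-vector over ``STANDARD_AA``; ``shift`` is an
    additive signed delta applied to it (clipped at zero, renormalized).
    Protein lengths are log-normal with ``length_log_mean`` /
    ``length_log_sigma`` on the log scale (default median 400 residues).
    """

    baseline_freqs: np.ndarray = field(default_factory=background_vector)
    shift: np.ndarray = field(default_factory=lambda: np.zeros(20))
    n_proteins: int = 200
    length_log_mean: float = math.log(400.0)
    length_log_sigma: float = 0.35
    peptidase_fraction: float = 0.0
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_freqs = np.asarray(self.baseline_freqs, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.baseline_freqs.shape != (20,) or self.shift.shape != (20,):
            raise ValueError("frequency vectors must have length 20")
        if (self.baseline_freqs < 0).any():
            raise ValueError("baseline frequencies must be non-negative")
        if abs(self.baseline_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("baseline frequencies must sum to 1")
        if not 0.0 <= self.peptidase_fraction <= 1.0:
            raise ValueError("peptidase_fraction must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")

    def effective_freqs(self) -> np.ndarray:
        """Baseline plus shift, clipped at zero and renormalized to 1."""
        v = np.clip(self.baseline_freqs + self.shift, 0.0, None)
        if v.sum() == 0:
            raise ValueError("shift annihilates every frequency")
        return v / v.sum()

    def with_shift(self, deltas: dict[str, float]) -> "ProteomeRegime":
        shift = self.shift.copy()
        for aa, d in deltas.items():
            shift[STANDARD_AA.index(aa)] += d
        return replace(self, shift=shift)


@dataclass
class SimulationTruth:
    """Ground truth attached to generated inputs (exact partition of records)."""

    proteins: pd.DataFrame | None = None       # per-protein labels
    shift: np.ndarray | None = None            # true group frequency shift
    cavity_counts: dict[str, int] | None = None
    matrix_effect: np.ndarray | None = None


_AA_ARRAY = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)


def derive_seed(seed: int, salt: int) -> int:
    """Independent child seed for a sub-generator.

    Reusing one integer seed across two generators aligns their random
    streams, which can make 'independent' background sequences replicate
    reference material; deriving per-purpose child seeds avoids that.
    """
    return int(np.random.SeedSequence([int(seed), int(salt)]).generate_state(1)[0] & 0x7FFFFFFF)


def _draw_sequences(rng: np.random.Generator, lengths: np.ndarray,
                    freqs: np.ndarray) -> list[str]:
    """i.i.d. residue draws for a batch of proteins, one vectorized call."""
    total = int(lengths.sum())
    flat = rng.choice(20, size=total, p=freqs)
    chars = _AA_ARRAY[flat].tobytes().decode()
    out, pos = [], 0
    for n in lengths:
        out.append(chars[pos:pos + n])
        pos += n
    return out


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Uniform substitution over the 19 alternative residues, no indels."""
    if rate <= 0:
        return sequence
    idx = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    aa_idx = np.searchsorted(_AA_ARRAY, idx)  # STANDARD_AA is ascii-sorted
    hit = rng.random(idx.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the 19 alternatives: draw 0..18 and skip the original
        alt = rng.integers(0, 19, size=n_hit)
        orig = aa_idx[hit]
        alt = alt + (alt >= orig)
        idx[hit] = _AA_ARRAY[alt]
    return idx.tobytes().decode()


# ---------------------------------------------------------------------------
# reference library

def make_reference_library(families: list[tuple[str, str, int, int]],
                           seed: int = 0) -> list[ReferenceEntry]:
    """Annotated reference library of peptidase families.

    ``families`` is a list of (family_code, catalytic_letter, n_members,
    length). Members of one family descend from a common random ancestor by
    substitution at rate 0.05, so within-family pairwise divergence stays
    below ~10% in expectation while between-family identity is at the
    random-background level.
    """
    rng = np.random.default_rng(seed)
    freqs = background_vector()
    entries: list[ReferenceEntry] = []
    serial = 0
    for family_code, catalytic_letter, n_members, length in families:
        validate_family_code(family_code)
        if catalytic_letter != family_code[0]:
            raise ValueError(
                f"catalytic letter {catalytic_letter!r} inconsistent with {family_code!r}"
            )
        if n_members < 1:
            raise ValueError(f"family {family_code}: n_members must be >= 1")
        ancestor = _draw_sequences(rng, np.array([length]), freqs)[0]
        for _ in range(n_members):
            serial += 1
            entries.append(ReferenceEntry(
                id=f"SYN{serial:06d}",
                family_code=family_code,
                catalytic_letter=catalytic_letter,
                sequence=_mutate(rng, ancestor, 0.05),
            ))
    return entries


# ---------------------------------------------------------------------------
# proteomes

def make_proteome(regime: ProteomeRegime, reference: list[ReferenceEntry],
                  species_id: str, group_label: str
                  ) -> tuple[list[ProteinRecord], SimulationTruth]:
    """One synthetic proteome plus its exact truth table.

    floor(n_proteins × peptidase_fraction) records are mutated copies of
    randomly chosen reference members (family recorded in the truth table);
    the remainder are i.i.d. draws from the shifted frequency vector.
    """
    rng = np.random.default_rng(regime.seed)
    n_pep = math.floor(regime.n_proteins * regime.peptidase_fraction)
    if n_pep > 0 and not reference:
        raise ValueError("peptidase_fraction > 0 requires a non-empty reference library")
    n_bg = regime.n_proteins - n_pep

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []

    for i in range(n_pep):
        src = reference[int(rng.integers(len(reference)))]
        seq = _mutate(rng, src.sequence, regime.mutation_rate)
        pid = f"{species_id}_P{i + 1:05d}"
        records.append(ProteinRecord(pid, seq, species_id, group_label))
        truth_rows.append({"protein_id": pid, "species": species_id,
                           "group": group_label, "label": src.family_code,
                           "source_reference": src.id})

    if n_bg > 0:
        lengths = np.maximum(
            rng.lognormal(regime.length_log_mean, regime.length_log_sigma, n_bg)
            .round().astype(int), 30)
        seqs = _draw_sequences(rng, lengths, regime.effective_freqs())
        for i, seq in enumerate(seqs):
            pid = f"{species_id}_B{i + 1:05d}"
            records.append(ProteinRecord(pid, seq, species_id, group_label))
            truth_rows.append({"protein_id": pid, "species": species_id,
                               "group": group_label, "label": "background",
                               "source_reference": ""})

    truth = SimulationTruth(
        proteins=pd.DataFrame(truth_rows, columns=["protein_id", "species", "group",
                                                   "label", "source_reference"]),
        shift=regime.shift.copy(),
    )
    return records, truth


#: Compositional shift emulating the thermophilic signature: higher
#: Ala/Glu/Gly/Pro/Arg/Val, lower Cys/His/Ile/Lys/Met/Asn/Gln/Ser/Thr/Trp
#: (Asp, Phe, Leu, Tyr untouched). Deltas are generator parameters chosen so
#: the vector is balanced (6 x +0.005 = 10 x 0.003).
THERMOPHILIC_SHIFT: dict[str, float] = {
    **{aa: +0.005 for aa in "AEGPRV"},
    **{aa: -0.003 for aa in "CHIKMNQSTW"},
}


# ---------------------------------------------------------------------------
# count matrices

def make_count_matrix(n_group1: int, n_group2: int, base_profile: dict[str, float],
                      effect: dict[str, float] | None = None,
                      dispersion: float = 0.2, seed: int = 0,
                      group_names: tuple[str, str] = ("mesophilic", "thermophilic"),
                      ) -> tuple[CountMatrix, SimulationTruth]:
    """Species-by-category counts from a gamma-Poisson (negative binomial) law.

    Group 2 means are the base profile times the per-category ``effect``
    factor (default all 1). ``dispersion`` is the gamma shape inverse; at 0
    the counts are exactly Poisson.
    """
    if n_group1 < 1 or n_group2 < 1:
        raise ValueError("both groups need at least one species")
    cats = list(base_profile)
    base = np.array([base_profile[c] for c in cats], dtype=float)
    if (base <= 0).any():
        raise ValueError("base profile means must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    eff = np.ones(len(cats))
    if effect:
        for c, f in effect.items():
            eff[cats.index(c)] = f

    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], {}
    for g, (n, mean) in enumerate([(n_group1, base), (n_group2, base * eff)]):
        for i in range(n):
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
            else:
                lam = mean
            rows.append(rng.poisson(lam))
            label = f"{group_names[g]}_{i + 1:02d}"
            labels.append(label)
            groups[label] = group_names[g]
    counts = pd.DataFrame(np.array(rows, dtype=int), index=labels, columns=cats)
    return CountMatrix(counts, pd.Series(groups)), SimulationTruth(matrix_effect=eff)


# ---------------------------------------------------------------------------
# structures

def make_structure(n_cavities: int, shell_radius_A: float = 8.0,
                   atom_spacing_A: float = 1.8, seed: int = 0,
                   source_id: str = "synthetic",
                   centers: np.ndarray | None = None
                   ) -> tuple[StructureModel, SimulationTruth]:
    """Atom slab containing exactly ``n_cavities`` disjoint hollow shells.

    Carbon atoms sit on a jittered cubic lattice; spherical interiors of
    radius ``shell_radius_A`` are carved out around well-separated centers,
    so the surviving lattice forms watertight shells around known voids.
    ``atom_spacing_A`` must not exceed 2.8 Å (twice the default probe
    radius) or the shells stop being watertight at the default grid.
    """
    if n_cavities < 0:
        raise ValueError("n_cavities must be non-negative")
    if atom_spacing_A <= 0 or atom_spacing_A > 2.8:
        raise ValueError("atom_spacing_A must lie in (0, 2.8] to keep shells watertight")
    rng = np.random.default_rng(seed)
    margin = 3.0 * atom_spacing_A
    if n_cavities == 0:
        half = 4.0 * atom_spacing_A
        lo = np.array([-half, -half, -half])
        hi = np.array([half, half, half])
        centers = np.empty((0, 3))
    else:
        if centers is None:
            pitch = 2.0 * shell_radius_A + 2.0 * margin
            centers = np.array([[i * pitch, 0.0, 0.0] for i in range(n_cavities)])
        else:
            centers = np.asarray(centers, dtype=float)
            if centers.shape != (n_cavities, 3):
                raise ValueError("centers must be an (n_cavities, 3) array")
            for i in range(n_cavities):
                for j in range(i + 1, n_cavities):
                    if np.linalg.norm(centers[i] - centers[j]) < 2.0 * (shell_radius_A + atom_spacing_A):
                        raise ValueError(f"shells {i} and {j} overlap: impossible packing")
        lo = centers.min(axis=0) - shell_radius_A - margin
        hi = centers.max(axis=0) + shell_radius_A + margin

    axes = [np.arange(lo[d], hi[d] + atom_spacing_A / 2, atom_spacing_A) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts + rng.uniform(-0.05, 0.05, pts.shape) * atom_spacing_A
    keep = np.ones(pts.shape[0], dtype=bool)
    for c in centers:
        keep &= np.linalg.norm(pts - c, axis=1) >= shell_radius_A
    pts = pts[keep]

    model = StructureModel(
        source_id=source_id,
        elements=["C"] * pts.shape[0],
        coords=pts,
        radii=np.full(pts.shape[0], radius_for_element("C")),
    )
    return model, SimulationTruth(cavity_counts={source_id: n_cavities})


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal fixed-column PDB (ATOM records with element column)."""
    with open(path, "w") as fh:
        for i, (el, (x, y, z)) in enumerate(zip(model.elements, model.coords), start=1):
            name = el.upper().rjust(2) + "  "
            fh.write(
                f"ATOM  {i % 100000:5d} {name:<4s} DUM A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el.upper():>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# hallmark sets

_SAFE_ALPHABET = "ACEFHIKLMNPQRSTVWY"  # no D, no G: cannot form any hallmark motif
_SAFE_NO_Y = _SAFE_ALPHABET.replace("Y", "")
_HYDRO = "AFILMV"


def _bg(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _motif(rng: np.random.Generator, kind: str) -> str:
    if kind == "dtg":
        return "D" + ("TS"[rng.integers(2)]) + "G"
    if kind == "y":
        return "Y"
    if kind == "xxg":
        return _HYDRO[rng.integers(6)] + _HYDRO[rng.integers(6)] + "G"
    raise ValueError(kind)


def make_hallmark_set(n_pos: int, n_neg: int, seed: int = 0
                      ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Labeled sequence set for the hallmark scan, truth by construction.

    Positives contain all five motifs in order. Each negative omits exactly
    one motif class instance; its background is drawn from an alphabet that
    cannot form the omitted (or any accidental) motif, so failure is
    guaranteed without consulting the scanner.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("set sizes must be non-negative")
    rng = np.random.default_rng(seed)
    kinds = ("dtg", "y", "xxg", "dtg", "xxg")
    records, rows = [], []

    for i in range(n_pos):
        parts = []
        for kind in kinds:
            parts.append(_bg(rng, int(rng.integers(5, 25)), _SAFE_ALPHABET))
            parts.append(_motif(rng, kind))
        parts.append(_bg(rng, int(rng.integers(5, 25)), _SAFE_ALPHABET))
        pid = f"POS{i + 1:04d}"
        records.append(ProteinRecord(pid, "".join(parts)))
        rows.append({"id": pid, "functional": True, "missing_motif": 0})

    for i in range(n_neg):
        missing = int(rng.integers(1, 6))  # 1-based index of the omitted motif
        alphabet = _SAFE_NO_Y if missing == 2 else _SAFE_ALPHABET
        parts = []
        for m, kind in enumerate(kinds, start=1):
            parts.append(_bg(rng, int(rng.integers(5, 25)), alphabet))
            if m != missing:
                parts.append(_motif(rng, kind))
        parts.append(_bg(rng, int(rng.integers(5, 25)), alphabet))
        pid = f"NEG{i + 1:04d}"
        records.append(ProteinRecord(pid, "".join(parts)))
        rows.append({"id": pid, "functional": False, "missing_motif": missing})

    truth = pd.DataFrame(rows, columns=["id", "functional", "missing_motif"])
    return records, truth
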