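"""Structure-level metrics: cavity counting, secondary-structure record
counts, and sequence-derived molecular weight / isoelectric point.

Cavities are detected on a regular voxel grid: every voxel within
(van der Waals radius + probe radius) of an atom center is occupied, the
exterior is identified by flood fill from the grid boundary, and each
remaining connected empty component of at least ``min_voxels`` voxels is an
internal cavity (6-connectivity). Absolute cavity counts therefore depend
on (grid_res, probe_radius, min_voxels); group comparisons should hold the
parameters fixed across structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw
from scipy import ndimage

from .amino import (
    ACIDIC_SIDECHAINS,
    BASIC_SIDECHAINS,
    PKA_CTERM,
    PKA_NTERM,
    PKA_SIDECHAIN,
    STANDARD_AA,
)
from .stats import KWResult, kruskal_wallis

#: Van der Waals radii (Å) for common elements; anything else gets the default.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_RADIUS: float = 1.70


@dataclass
class StructureModel:
    """Atom coordinates with radii plus secondary-structure record counts."""

    source_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) in Å
    radii: np.ndarray   # (n_atoms,) in Å
    helix_record_count: int = 0
    sheet_strand_record_count: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite atom coordinates")
        if (self.radii <= 0).any():
            raise ValueError("atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


def radius_for_element(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def read_pdb(path: str | Path, skip_waters: bool = True) -> StructureModel:
    """Parse a fixed-column PDB file into a :class:`StructureModel`.

    ATOM and HETATM records are read (waters skipped by default); the
    element is taken from columns 77-78 with a fallback heuristic from the
    atom name; HELIX records and SHEET (strand) records are counted.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse PDB file {path.name}: {exc}") from exc
    elements: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for model in st:
        for chain in model:
            for residue in chain:
                if skip_waters and residue.is_water():
                    continue
                for atom in residue:
                    el = atom.element.name if atom.element.name else "C"
                    elements.append(el)
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    radii.append(radius_for_element(el))
        break  # first model only
    if not elements:
        raise ValueError(f"no ATOM records in {path.name}")
    n_strands = sum(len(sheet.strands) for sheet in st.sheets)
    return StructureModel(
        source_id=path.stem,
        elements=elements,
        coords=np.array(xyz),
        radii=np.array(radii),
        helix_record_count=len(st.helices),
        sheet_strand_record_count=n_strands,
    )


@dataclass
class CavityReport:
    n_cavities: int
    voxel_counts: list[int]
    volumes: list[float]  # Å³
    grid_res: float
    probe_radius: float
    min_voxels: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.n_cavities != len(self.volumes):
            raise ValueError("cavity count must equal length of the volume list")


def count_cavities(model: StructureModel, grid_res: float = 0.8,
                   probe_radius: float = 1.4, min_voxels: int = 5,
                   max_grid_voxels: int = 60_000_000) -> CavityReport:
    """Probe-augmented grid flood-fill cavity detection."""
    if model.n_atoms == 0:
        raise ValueError("structure has no atoms")
    pad = float(model.radii.max() + probe_radius) + 2 * grid_res
    lo = model.coords.min(axis=0) - pad
    hi = model.coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / grid_res).astype(int) + 1
    if int(np.prod(shape)) > max_grid_voxels:
        raise ValueError(
            f"voxel grid of {int(np.prod(shape)):,} cells exceeds the budget; "
            "use a coarser grid_res"
        )

    occupied = np.zeros(shape, dtype=bool)
    # mark the sphere of each atom on a local sub-grid
    for center, radius in zip(model.coords, model.radii):
        r = radius + probe_radius
        imin = np.floor((center - r - lo) / grid_res).astype(int)
        imax = np.ceil((center + r - lo) / grid_res).astype(int) + 1
        imin = np.maximum(imin, 0)
        imax = np.minimum(imax, shape)
        ax = [lo[d] + np.arange(imin[d], imax[d]) * grid_res - center[d] for d in range(3)]
        dist2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                 + ax[2][None, None, :] ** 2)
        occupied[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] |= dist2 <= r * r

    empty = ~occupied
    struct6 = ndimage.generate_binary_structure(3, 1)
    labels, n_comp = ndimage.label(empty, structure=struct6)
    # components touching any face of the grid are exterior
    boundary = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ]))
    exterior = set(boundary[boundary > 0].tolist())
    sizes = ndimage.sum_labels(empty, labels, index=np.arange(1, n_comp + 1))
    voxel_counts = sorted(
        (int(sz) for comp, sz in enumerate(sizes, start=1)
         if comp not in exterior and sz >= min_voxels),
        reverse=True,
    )
    vol = grid_res ** 3
    return CavityReport(
        n_cavities=len(voxel_counts),
        voxel_counts=voxel_counts,
        volumes=[c * vol for c in voxel_counts],
        grid_res=grid_res,
        probe_radius=probe_radius,
        min_voxels=min_voxels,
        source_id=model.source_id,
    )


# ---------------------------------------------------------------------------
# sequence-level metrics

def _check_standard(sequence: str) -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(seq, start=1):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
    return seq


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    seq = _check_standard(sequence)
    return _bio_mw(seq, seq_type="protein", monoisotopic=False) / 1000.0


def net_charge(sequence: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH, EMBOSS pKa set."""
    seq = _check_standard(sequence)
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    def neg(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pka - pH))
    charge = pos(PKA_NTERM) - neg(PKA_CTERM)
    for aa in seq:
        if aa in BASIC_SIDECHAINS:
            charge += pos(PKA_SIDECHAIN[aa])
        elif aa in ACIDIC_SIDECHAINS:
            charge -= neg(PKA_SIDECHAIN[aa])
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4, max_iter: int = 60) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Net charge is monotone non-increasing in pH, so bisection converges; the
    returned pH satisfies |charge| < tol (or the bracket midpoint after
    ``max_iter`` halvings, whichever comes first).
    """
    seq = _check_standard(sequence)
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) < 0:
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def structure_report(models: list[StructureModel], sequences: dict[str, str] | None = None,
                     grid_res: float = 0.8, probe_radius: float = 1.4,
                     min_voxels: int = 5) -> pd.DataFrame:
    """Per-structure metric table (helix/strand records, cavities, Mw/pI)."""
    rows = []
    for model in models:
        report = count_cavities(model, grid_res, probe_radius, min_voxels)
        row = {
            "id": model.source_id,
            "n_atoms": model.n_atoms,
            "helix_records": model.helix_record_count,
            "sheet_strand_records": model.sheet_strand_record_count,
            "n_cavities": report.n_cavities,
            "cavity_volume_total": sum(report.volumes),
        }
        if sequences and model.source_id in sequences:
            seq = sequences[model.source_id]
            row["mw_kda"] = molecular_weight(seq)
            row["pI"] = isoelectric_point(seq)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_structural_groups(values_by_group: dict[str, list[float]],
                              n_perm: int | None = None,
                              seed: int | None = None) -> KWResult:
    """Kruskal-Wallis comparison of a structural metric between groups."""
    return kruskal_wallis(list(values_by_group.values()), n_perm=n_perm, seed=seed)
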