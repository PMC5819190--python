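"""Amino-acid composition profiles and group comparison tests.

Fractions are percentages over the standard 20 residues only; ambiguity
codes (B, J, O, U, X, Z) are excluded from both numerator and denominator.
The physicochemical class fractions follow the overlapping EMBOSS PEPSTATS
sets, so charged + polar + hydrophobic does not sum to 100 by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .amino import CHARGED, HYDROPHOBIC, POLAR, STANDARD_AA, encode
from .records import ProteinRecord
from .stats import TestResult, t_test

CLASS_NAMES = ("charged", "polar", "hydrophobic")
VARIABLES = tuple(STANDARD_AA) + CLASS_NAMES

_CLASS_MASKS = {
    "charged": np.array([aa in CHARGED for aa in STANDARD_AA]),
    "polar": np.array([aa in POLAR for aa in STANDARD_AA]),
    "hydrophobic": np.array([aa in HYDROPHOBIC for aa in STANDARD_AA]),
}


@dataclass(frozen=True)
class CompositionProfile:
    """Percent composition of one unit (a protein or a species mean)."""

    unit_id: str
    fractions: np.ndarray  # percent per residue, STANDARD_AA order
    charged: float
    polar: float
    hydrophobic: float
    n_residues: int

    def as_series(self) -> pd.Series:
        vals = np.concatenate([self.fractions, [self.charged, self.polar, self.hydrophobic]])
        return pd.Series(vals, index=list(VARIABLES), name=self.unit_id)


def _counts(sequence: str) -> np.ndarray:
    idx = encode(sequence)
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError("sequence contains no standard amino-acid residue")
    return np.bincount(idx, minlength=20).astype(float)


def _profile_from_counts(unit_id: str, counts: np.ndarray) -> CompositionProfile:
    n = int(counts.sum())
    frac = counts / counts.sum() * 100.0
    return CompositionProfile(
        unit_id=unit_id,
        fractions=frac,
        charged=float(frac[_CLASS_MASKS["charged"]].sum()),
        polar=float(frac[_CLASS_MASKS["polar"]].sum()),
        hydrophobic=float(frac[_CLASS_MASKS["hydrophobic"]].sum()),
        n_residues=n,
    )


def aa_composition(sequence: str, unit_id: str = "") -> CompositionProfile:
    """Percent amino-acid composition over the standard residues of one sequence."""
    return _profile_from_counts(unit_id, _counts(sequence))


def class_fractions(sequence: str) -> tuple[float, float, float]:
    """(charged, polar, hydrophobic) percentages of a sequence, EMBOSS classes."""
    p = aa_composition(sequence)
    return p.charged, p.polar, p.hydrophobic


def profile_proteins(records: list[ProteinRecord]) -> pd.DataFrame:
    """Per-protein profile table (rows: proteins; columns: 20 residues + classes)."""
    rows = [aa_composition(r.sequence, r.id).as_series() for r in records]
    return pd.DataFrame(rows)


def species_profile(records: list[ProteinRecord], species: str = "",
                    weighted: bool = False) -> CompositionProfile:
    """Aggregate a proteome into one species profile.

    Unweighted (default): mean of per-protein percent fractions, each protein
    counting equally regardless of length. Weighted: pooled residue counts
    across the proteome (equivalent to length-weighting).
    """
    if not records:
        raise ValueError("empty proteome")
    if weighted:
        total = np.zeros(20)
        for r in records:
            total += _counts(r.sequence)
        return _profile_from_counts(species, total)
    per_protein = np.stack([_counts(r.sequence) for r in records])
    frac = per_protein / per_protein.sum(axis=1, keepdims=True) * 100.0
    mean_frac = frac.mean(axis=0)
    prof = _profile_from_counts(species, mean_frac)  # already sums to 100
    return CompositionProfile(
        unit_id=species, fractions=prof.fractions, charged=prof.charged,
        polar=prof.polar, hydrophobic=prof.hydrophobic,
        n_residues=int(per_protein.sum()),
    )


def profiles_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_series() for p in profiles])


def compare_groups(profiles: pd.DataFrame, groups: pd.Series,
                   group_pair: tuple[str, str], mode: str = "welch",
                   alpha: float = 0.05, adjust: bool = False) -> pd.DataFrame:
    """Per-variable two-group tests on a profile table.

    Rows of ``profiles`` are units (proteins or species means) with the 23
    composition variables as columns; ``group_pair`` = (focal, baseline) so a
    "+" direction means higher in the focal group (e.g. thermophilic).
    Returns a long-format table of :class:`~thermopep.stats.TestResult`
    fields; raw P is primary, Benjamini-Hochberg adjusted P optional.
    """
    groups = pd.Series(groups).reindex(profiles.index)
    gx, gy = group_pair
    x = profiles.loc[(groups == gx).to_numpy()]
    y = profiles.loc[(groups == gy).to_numpy()]
    if mode == "paired" and x.shape[0] != y.shape[0]:
        raise ValueError(
            "paired mode requires matched unit lists of equal length in both groups"
        )
    xa = x.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    if xa.shape[0] < 2 or ya.shape[0] < 2:
        raise ValueError("need at least 2 units per group")

    # vectorized across variables; semantics identical to stats.t_test
    import warnings

    from scipy import stats as sps
    if mode == "paired":
        d = xa - ya
        degenerate = (np.ptp(d, axis=0) == 0) & (d[0] != 0)
        if degenerate.any():
            bad = list(profiles.columns[degenerate])
            raise ValueError(f"degenerate paired data (zero-variance non-zero differences): {bad}")
        with warnings.catch_warnings():
            # constant columns are handled explicitly below; silence scipy's
            # catastrophic-cancellation warning for them
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_rel(xa, ya, axis=0)
        stat, p = res.statistic, res.pvalue
        df = np.full(xa.shape[1], float(xa.shape[0] - 1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(xa, ya, axis=0, equal_var=(mode == "student"))
        stat, p = res.statistic, res.pvalue
        df = np.asarray(res.df, dtype=float)

    mean_x, mean_y = xa.mean(axis=0), ya.mean(axis=0)
    diff = mean_x - mean_y
    constant = (np.ptp(xa, axis=0) == 0) & (np.ptp(ya, axis=0) == 0) & (mean_x == mean_y)
    stat = np.where(constant, 0.0, stat)
    p = np.where(constant, 1.0, p)
    df = np.where(constant, float(xa.shape[0] + ya.shape[0] - 2), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    direction = np.where(p >= alpha, "ns", np.where(diff > 0, "+", "-"))

    out = pd.DataFrame({
        "variable": [str(v) for v in profiles.columns],
        f"mean_{gx}": mean_x,
        f"mean_{gy}": mean_y,
        "difference": diff,
        "t": stat,
        "df": df,
        "p_value": p,
        "direction": direction,
    })
    if adjust:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
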