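"""Canned study-level experiments shared by the analysis scripts, the
acceptance checks and the test suite.

Each function recomputes its result from scratch — nothing is cached or
hard-coded — so the same call is usable both as an analysis driver step and
as an independent check.
"""

from __future__ import annotations

import pandas as pd

from .composition import compare_groups, profiles_table, species_profile
from .datasets import (
    MESOPHILIC,
    SEVEN_TYPES,
    THERMOPHILIC,
    cavity_counts_by_group,
    load_peptidase_counts,
)
from .matrix import CountMatrix
from .stats import AnosimResult, KWResult, anosim, kruskal_wallis, matrix_distances, simper
from .synthetic import (
    THERMOPHILIC_SHIFT,
    ProteomeRegime,
    derive_seed,
    make_count_matrix,
    make_proteome,
)

GROUP_PAIR = (MESOPHILIC, THERMOPHILIC)


def census_two_group(matrix: CountMatrix | None = None) -> CountMatrix:
    matrix = matrix or load_peptidase_counts()
    return matrix.subset_groups(list(GROUP_PAIR))


def simper_sensitivity_grid(matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Overall SIMPER dissimilarity across the 2x2 sensitivity grid.

    Grid axes: raw counts vs row percentages, and all 9 categories vs the 7
    mechanistic catalytic types (dropping Mixed and Unknown).
    """
    two = census_two_group(matrix)
    rows = []
    for relativize in (False, True):
        for cats, cat_label in ((two.categories, "all_9"),
                                (list(SEVEN_TYPES), "seven_types")):
            sub = two.subset_categories(cats)
            res = simper(sub, GROUP_PAIR, relativize=relativize)
            rows.append({
                "input": "row_percent" if relativize else "raw_counts",
                "categories": cat_label,
                "overall_percent": res.overall,
            })
    return pd.DataFrame(rows)


def headline_simper(matrix: CountMatrix | None = None) -> float:
    """Overall between-group dissimilarity (%) on raw counts, all categories."""
    return simper(census_two_group(matrix), GROUP_PAIR).overall


def headline_anosim(n_perm: int = 9999, seed: int = 42,
                    matrix: CountMatrix | None = None) -> AnosimResult:
    """ANOSIM (Bray-Curtis on raw counts) on the bundled census."""
    two = census_two_group(matrix)
    dm = matrix_distances(two)
    return anosim(dm, two.groups.to_numpy(), n_perm=n_perm, seed=seed)


def cavity_kw(n_perm: int = 500_000, seed: int = 42) -> KWResult:
    """Kruskal-Wallis on the bundled cavity-count vectors (meso vs thermo)."""
    cav = cavity_counts_by_group()
    return kruskal_wallis([cav[MESOPHILIC], cav[THERMOPHILIC]],
                          n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# compositional direction recovery

INCREASED_RESIDUES = tuple("AEGPRV")
EXPECTED_CLASS_DIRECTIONS = {"charged": "+", "hydrophobic": "+", "polar": "-"}


def composition_direction_replicate(seed: int, n_species: int = 10,
                                    n_proteins: int = 150,
                                    alpha: float = 0.05) -> dict:
    """One synthetic two-group composition experiment.

    Generates ``n_species`` mesophilic proteomes from the baseline regime
    and ``n_species`` thermophilic ones with the thermophilic shift, then
    tests thermophilic − mesophilic per variable (Welch on species means).
    Returns which planted signals were recovered.
    """
    profiles, labels = [], {}
    for g, group in enumerate(GROUP_PAIR):
        for i in range(n_species):
            sp = f"{group}_{i}"
            regime = ProteomeRegime(
                n_proteins=n_proteins,
                seed=derive_seed(seed, 100 * (g + 1) + i),
            )
            if group == THERMOPHILIC:
                regime = regime.with_shift(THERMOPHILIC_SHIFT)
            recs, _ = make_proteome(regime, [], sp, group)
            profiles.append(species_profile(recs, sp))
            labels[sp] = group
    table = profiles_table(profiles)
    out = compare_groups(table, pd.Series(labels),
                         (THERMOPHILIC, MESOPHILIC), alpha=alpha)
    out = out.set_index("variable")
    residues_ok = all(out.loc[aa, "direction"] == "+" for aa in INCREASED_RESIDUES)
    classes_ok = all(out.loc[var, "direction"] == want
                     for var, want in EXPECTED_CLASS_DIRECTIONS.items())
    return {"residues_ok": residues_ok, "classes_ok": classes_ok, "table": out}


def composition_direction_experiment(n_replicates: int = 100, seed: int = 0,
                                     n_species: int = 10,
                                     n_proteins: int = 150) -> dict:
    """Replicated direction-recovery rates for the planted shift."""
    res_hits = cls_hits = both = 0
    for r in range(n_replicates):
        rep = composition_direction_replicate(derive_seed(seed, 7000 + r),
                                              n_species=n_species,
                                              n_proteins=n_proteins)
        res_hits += rep["residues_ok"]
        cls_hits += rep["classes_ok"]
        both += rep["residues_ok"] and rep["classes_ok"]
    return {
        "n_replicates": n_replicates,
        "residue_rate": res_hits / n_replicates,
        "class_rate": cls_hits / n_replicates,
        "joint_rate": both / n_replicates,
    }


# ---------------------------------------------------------------------------
# ANOSIM null calibration

NULL_BASE_PROFILE = {
    "Serine": 120.0, "Aspartic": 30.0, "Metallo": 100.0,
    "Threonine": 25.0, "Cysteine": 80.0, "Glutamic": 3.0,
}


def anosim_null_calibration(n_matrices: int = 500, seed: int = 0,
                            n_perm: int = 199, alpha: float = 0.05,
                            n1: int = 6, n2: int = 6) -> float:
    """Type-I error rate of ANOSIM on null count matrices (no group effect)."""
    rejections = 0
    for i in range(n_matrices):
        m, _ = make_count_matrix(n1, n2, NULL_BASE_PROFILE,
                                 seed=derive_seed(seed, 9000 + i))
        dm = matrix_distances(m)
        res = anosim(dm, m.groups.to_numpy(), n_perm=n_perm,
                     seed=derive_seed(seed, 50_000 + i))
        rejections += res.p_value <= alpha
    return rejections / n_matrices
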