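"""Unit and property tests of the profile statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.stats import kruskal as scipy_kruskal

from oracles import anosim_p_exhaustive, anosim_r_naive, kw_h_rank_sum, kw_p_exhaustive
from thermopep.matrix import CountMatrix
from thermopep.stats import (
    DistanceMatrix,
    anosim,
    bray_curtis,
    kruskal_wallis,
    matrix_distances,
    pairwise_distances,
    simper,
    t_test,
)
import pandas as pd


# ---------------------------------------------------------------------------
# Bray-Curtis

@pytest.mark.parametrize("x, y, expected", [
    ((3, 1, 4), (3, 1, 4), 0.0),       # identical vectors
    ((1, 0), (0, 1), 1.0),             # disjoint support
    ((2, 1), (1, 1), 0.2),             # hand evaluation of the formula
])
def test_bray_curtis_values(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)


def test_bray_curtis_undefined_and_invalid():
    with pytest.raises(ValueError, match="all-zero"):
        bray_curtis((0, 0), (0, 0))
    with pytest.raises(ValueError, match="non-negative"):
        bray_curtis((1, -1), (1, 1))
    with pytest.raises(ValueError, match="equal length"):
        bray_curtis((1, 2), (1, 2, 3))


def test_bray_curtis_matches_scipy(rng):
    for _ in range(50):
        x = rng.integers(0, 50, size=8)
        y = rng.integers(0, 50, size=8)
        if (x + y).sum() == 0:
            continue
        assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y), abs=1e-12)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1], [1, 0]]))


# ---------------------------------------------------------------------------
# ANOSIM

def _two_group_matrix(rng, n1=4, n2=4, ncat=5):
    counts = rng.integers(0, 60, size=(n1 + n2, ncat)) + 1
    labels = np.array(["g1"] * n1 + ["g2"] * n2)
    return counts.astype(float), labels


def test_anosim_maximal_separation():
    """All between-distances above all within-distances gives R = 1."""
    d = np.array([
        [0.0, 0.1, 0.9, 0.8],
        [0.1, 0.0, 0.85, 0.95],
        [0.9, 0.85, 0.0, 0.05],
        [0.8, 0.95, 0.05, 0.0],
    ])
    dm = DistanceMatrix(list("abcd"), d)
    res = anosim(dm, ["x", "x", "y", "y"], n_perm=99, seed=0)
    assert res.R == pytest.approx(1.0)


def test_anosim_rejects_singleton_group():
    dm = DistanceMatrix(list("abc"), np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
    with pytest.raises(ValueError, match="at least 2 members"):
        anosim(dm, ["x", "x", "y"], n_perm=9)


def test_anosim_r_matches_naive_oracle(rng):
    for _ in range(20):
        counts, labels = _two_group_matrix(rng)
        dm = pairwise_distances(counts)
        res = anosim(dm, labels, n_perm=9, seed=0)
        assert res.R == pytest.approx(anosim_r_naive(dm.data, labels), abs=1e-12)


def test_anosim_r_matches_scikit_bio(census_two_group):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    dm = matrix_distances(census_two_group)
    res = anosim(dm, census_two_group.groups.to_numpy(), n_perm=99, seed=0)
    sk = skbio_stats.anosim(
        skbio_stats.DistanceMatrix(dm.data, ids=dm.labels),
        grouping=list(census_two_group.groups),
        permutations=99,
    )
    assert res.R == pytest.approx(sk["test statistic"], abs=1e-12)


def test_anosim_sampled_p_converges_to_exhaustive(rng):
    """On n=8 units the 999-draw Monte-Carlo P sits within Monte-Carlo
    error of the full-enumeration P."""
    counts, labels = _two_group_matrix(rng, 4, 4)
    dm = pairwise_distances(counts)
    p_exact = anosim_p_exhaustive(dm.data, labels)
    res = anosim(dm, labels, n_perm=999, seed=7)
    se = np.sqrt(p_exact * (1 - p_exact) / 999)
    assert abs(res.p_value - p_exact) <= 3 * se + 2 / 1000


def test_anosim_invariant_to_row_order(census_two_group):
    order = np.random.default_rng(0).permutation(len(census_two_group.species))
    shuffled = CountMatrix(census_two_group.counts.iloc[order],
                           census_two_group.groups.iloc[order])
    r1 = anosim(matrix_distances(census_two_group),
                census_two_group.groups.to_numpy(), n_perm=9, seed=0).R
    r2 = anosim(matrix_distances(shuffled), shuffled.groups.to_numpy(),
                n_perm=9, seed=0).R
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_anosim_reproducible_given_seed(census_two_group):
    dm = matrix_distances(census_two_group)
    labels = census_two_group.groups.to_numpy()
    a = anosim(dm, labels, n_perm=999, seed=5)
    b = anosim(dm, labels, n_perm=999, seed=5)
    assert (a.R, a.p_value) == (b.R, b.p_value)


# ---------------------------------------------------------------------------
# SIMPER

def _matrix_from(counts, labels):
    idx = [f"s{i}" for i in range(len(labels))]
    return CountMatrix(pd.DataFrame(counts, index=idx,
                                    columns=[f"v{j}" for j in range(counts.shape[1])]),
                       pd.Series(dict(zip(idx, labels))))


def test_simper_single_pair_decomposes_bray_curtis(rng):
    counts = rng.integers(1, 40, size=(2, 6))
    m = _matrix_from(counts, ["a", "b"])
    res = simper(m, ("a", "b"))
    assert res.overall == pytest.approx(100 * bray_curtis(counts[0], counts[1]))
    assert res.table["average_contribution"].sum() == pytest.approx(res.overall)


def test_simper_contributions_sum_to_overall(rng):
    """Conservation: per-variable contributions decompose the overall
    average dissimilarity exactly, on randomly fuzzed matrices."""
    for _ in range(200):
        n1, n2 = rng.integers(1, 5, 2)
        ncat = rng.integers(2, 8)
        counts = rng.integers(0, 30, size=(n1 + n2, ncat)) + 1
        m = _matrix_from(counts, ["a"] * n1 + ["b"] * n2)
        res = simper(m, ("a", "b"))
        assert res.table["average_contribution"].sum() == pytest.approx(res.overall, abs=1e-9)
        assert res.table["cumulative_percent"].iloc[-1] == pytest.approx(100.0, abs=1e-6)


def test_simper_table_sorted_descending(census_two_group):
    res = simper(census_two_group, ("mesophilic", "thermophilic"))
    contrib = res.table["average_contribution"].to_numpy()
    assert (np.diff(contrib) <= 1e-12).all()


def test_simper_empty_group_errors(census_two_group):
    with pytest.raises(ValueError, match="non-empty"):
        simper(census_two_group, ("mesophilic", "psychrophilic"))


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def test_kw_matches_scipy_with_ties(rng):
    for _ in range(20):
        groups = [rng.integers(0, 8, size=rng.integers(3, 9)) for _ in range(3)]
        res = kruskal_wallis(groups)
        expected = scipy_kruskal(*groups)
        assert res.H == pytest.approx(expected.statistic, abs=1e-10)
        assert res.p_chi2 == pytest.approx(expected.pvalue, abs=1e-10)
        assert res.H == pytest.approx(kw_h_rank_sum(groups), abs=1e-10)


def test_kw_rank_invariance():
    a = kruskal_wallis([[1, 2], [3, 4]])
    b = kruskal_wallis([[10, 20], [30, 40]])
    assert a.H == pytest.approx(b.H)


def test_kw_all_identical_values():
    res = kruskal_wallis([[5, 5], [5, 5, 5]], n_perm=99, seed=0)
    assert res.H == 0.0 and res.p_chi2 == 1.0 and res.p_perm == 1.0


def test_kw_three_singletons_attains_enumerable_maximum():
    """With 3 groups of one distinct value each (N=3), every H over the 6
    arrangements equals the same maximal value, so the observed H must
    equal the enumeration maximum."""
    import itertools
    h_obs = kruskal_wallis([[1], [2], [3]]).H
    h_all = [kw_h_rank_sum([[a], [b], [c]])
             for a, b, c in itertools.permutations([1, 2, 3])]
    assert h_obs == pytest.approx(max(h_all), abs=1e-12)


def test_kw_permutation_p_matches_exhaustive(rng):
    """Monte-Carlo permutation P within 3 standard errors of the exact
    enumeration P on N=10."""
    x = rng.integers(0, 10, size=4).tolist()
    y = (rng.integers(0, 10, size=6) + 2).tolist()
    p_exact = kw_p_exhaustive(x, y)
    res = kruskal_wallis([x, y], n_perm=20000, seed=11)
    se = np.sqrt(p_exact * (1 - p_exact) / 20000)
    assert abs(res.p_perm - p_exact) <= 3 * se + 1e-4


def test_kw_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], []])


# ---------------------------------------------------------------------------
# t tests

def test_welch_matches_hand_formula():
    """Welch statistic and Welch-Satterthwaite df recomputed by hand."""
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 4.0, 8.0])
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / 3 + vy / 3
    t_hand = (x.mean() - y.mean()) / np.sqrt(se2)
    df_hand = se2 ** 2 / ((vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2)
    res = t_test(x, y, mode="welch")
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.df == pytest.approx(df_hand, abs=1e-9)


def test_t_identical_groups():
    res = t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.direction == "ns"


def test_t_paired_degenerate_differences():
    with pytest.raises(ValueError, match="degenerate"):
        t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], mode="paired")


def test_t_paired_requires_matched_units():
    with pytest.raises(ValueError, match="matched"):
        t_test([1.0, 2.0], [1.0, 2.0, 3.0], mode="paired")


def test_t_direction_sign():
    res = t_test([10.0, 11, 12, 11], [1.0, 2, 1, 2], mode="welch")
    assert res.direction == "+" and res.difference > 0
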