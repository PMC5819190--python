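"""Community-profile statistics on count matrices.

Bray-Curtis dissimilarity, the ANOSIM rank permutation test, SIMPER
contribution decomposition and the tie-corrected Kruskal-Wallis test are
authored here from first principles (they are the analytical core of the
profile comparison); the chi-square survival function and rank assignment
come from scipy. Permutation P values use the "+1 in numerator and
denominator" convention throughout, so a reported P is never zero and is
bounded below by 1/(n_perm+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .matrix import CountMatrix

DEFAULT_N_PERM = 9999


# ---------------------------------------------------------------------------
# Bray-Curtis

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y) of two non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def _euclidean(x, y) -> float:
    return float(np.linalg.norm(np.asarray(x, float) - np.asarray(y, float)))

_METRICS = {"braycurtis": bray_curtis, "euclidean": _euclidean}


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def pairwise_distances(rows: np.ndarray, labels: list[str] | None = None,
                       metric: str = "braycurtis") -> DistanceMatrix:
    """All-pairs distance matrix of the rows of a profile matrix."""
    rows = np.asarray(rows, dtype=float)
    fn = _METRICS[metric]
    n = rows.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(rows[i], rows[j])
    if labels is None:
        labels = [str(i) for i in range(n)]
    return DistanceMatrix(list(labels), d, metric)


def matrix_distances(matrix: CountMatrix, metric: str = "braycurtis",
                     relativize: bool = False) -> DistanceMatrix:
    return pairwise_distances(matrix.values(relativize=relativize),
                              matrix.species, metric)


# ---------------------------------------------------------------------------
# ANOSIM

@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    metric: str
    n_units: int


def _anosim_r_from_ranks(ranks: np.ndarray, between: np.ndarray, m_half: float) -> float:
    return float((ranks[between].mean() - ranks[~between].mean()) / m_half)


def anosim(dm: DistanceMatrix, labels, n_perm: int = DEFAULT_N_PERM,
           seed: int | None = None) -> AnosimResult:
    """Clarke's analysis of similarities on a distance matrix.

    All n(n−1)/2 off-diagonal distances are ranked (mid-ranks on ties);
    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2. Significance by permuting the group labels.
    """
    labels = np.asarray(labels)
    n = dm.data.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one label per unit required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"every group needs at least 2 members; too small: {list(small)}")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    m_half = (n * (n - 1) / 2) / 2.0
    group_idx = np.searchsorted(uniq, labels)

    between = group_idx[iu[0]] != group_idx[iu[1]]
    r_obs = _anosim_r_from_ranks(ranks, between, m_half)

    # permutations preserve group sizes, so the between-pair count is constant
    n_between = int(between.sum())
    n_within = ranks.shape[0] - n_between
    rank_total = ranks.sum()
    rng = np.random.default_rng(seed)
    n_ge = 0
    block = 10_000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm_labels = group_idx[order]
        btw = perm_labels[:, iu[0]] != perm_labels[:, iu[1]]
        sum_btw = btw @ ranks
        r_perm = (sum_btw / n_between - (rank_total - sum_btw) / n_within) / m_half
        n_ge += int((r_perm >= r_obs - 1e-12).sum())
        done += b
    p = (n_ge + 1) / (n_perm + 1)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_perm, seed=seed,
                        metric=dm.metric, n_units=n)


# ---------------------------------------------------------------------------
# SIMPER

@dataclass
class SimperResult:
    """Decomposition of average between-group Bray-Curtis dissimilarity.

    ``overall`` is in percent; the per-variable table is ranked by
    descending contribution (lexicographic tie-break on variable name).
    """

    overall: float
    group_pair: tuple[str, str]
    table: pd.DataFrame = field(repr=False)


def simper(matrix: CountMatrix, group_pair: tuple[str, str],
           relativize: bool = False) -> SimperResult:
    """Similarity-percentage analysis between two groups of a count matrix.

    For each cross-group pair of rows (j, k), variable v contributes
    |x_vj − x_vk| / Σ_u(x_uj + x_uk); contributions are averaged over all
    cross-group pairs and sum exactly to the overall average Bray-Curtis
    dissimilarity.
    """
    g1, g2 = group_pair
    rows1 = matrix.values(relativize=relativize)[(matrix.groups == g1).to_numpy()]
    rows2 = matrix.values(relativize=relativize)[(matrix.groups == g2).to_numpy()]
    if rows1.shape[0] == 0 or rows2.shape[0] == 0:
        raise ValueError(f"both groups must be non-empty: {group_pair}")

    # pairwise |x-y| and totals, vectorized over the cross product
    diff = np.abs(rows1[:, None, :] - rows2[None, :, :])        # (n1, n2, v)
    denom = (rows1[:, None, :] + rows2[None, :, :]).sum(axis=2)  # (n1, n2)
    if (denom == 0).any():
        raise ValueError("a cross-group pair of all-zero rows makes Bray-Curtis undefined")
    contrib = (diff / denom[:, :, None]).mean(axis=(0, 1)) * 100.0
    overall = float(contrib.sum())

    table = pd.DataFrame({
        "variable": matrix.categories,
        "average_contribution": contrib,
    })
    table["percent_contribution"] = table["average_contribution"] / overall * 100.0
    table = table.sort_values(
        ["average_contribution", "variable"], ascending=[False, True]
    ).reset_index(drop=True)
    table["cumulative_percent"] = table["percent_contribution"].cumsum()
    return SimperResult(overall=overall, group_pair=(g1, g2), table=table)


# ---------------------------------------------------------------------------
# Kruskal-Wallis

@dataclass
class KWResult:
    H: float
    df: int
    p_chi2: float
    p_perm: float | None
    n_permutations: int
    seed: int | None


def _kw_h(values: np.ndarray, sizes: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H of concatenated group values."""
    n_total = values.shape[0]
    ranks = rankdata(values)
    h = 0.0
    start = 0
    for sz in sizes:
        h += ranks[start:start + sz].sum() ** 2 / sz
        start += sz
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n_total ** 3 - n_total)
    if correction == 0.0:  # all observations identical
        return 0.0
    return h / correction


def kruskal_wallis(groups: list, n_perm: int | None = None,
                   seed: int | None = None) -> KWResult:
    """Rank-based k-group location test with tie correction.

    P is computed from the chi-square approximation (df = k−1) and, when
    ``n_perm`` is given, also by Monte-Carlo label shuffles with the +1
    convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([a.shape[0] for a in arrays])
    if sizes.min() < 1 or sizes.sum() < 3:
        raise ValueError("need non-empty groups and total N >= 3")
    values = np.concatenate(arrays)
    df = len(arrays) - 1

    h_obs = _kw_h(values, sizes)
    if np.unique(values).size == 1:
        return KWResult(H=0.0, df=df, p_chi2=1.0, p_perm=1.0 if n_perm else None,
                        n_permutations=n_perm or 0, seed=seed)
    p_chi2 = float(sps.chi2.sf(h_obs, df))

    p_perm = None
    if n_perm:
        rng = np.random.default_rng(seed)
        # permuting ranks is equivalent to permuting observations
        ranks = rankdata(values)
        n_total = values.shape[0]
        _, tie_counts = np.unique(values, return_counts=True)
        correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n_total ** 3 - n_total)
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        n_ge = 0
        # vectorized in blocks: random permutations via argsort of uniforms
        block = 20000
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            order = np.argsort(rng.random((b, n_total)), axis=1)
            permuted = ranks[order]
            h = np.zeros(b)
            for s, sz in zip(starts, sizes):
                h += permuted[:, s:s + sz].sum(axis=1) ** 2 / sz
            h = (12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)) / correction
            n_ge += int((h >= h_obs - 1e-9).sum())
            done += b
        p_perm = (n_ge + 1) / (n_perm + 1)

    return KWResult(H=float(h_obs), df=df, p_chi2=p_chi2, p_perm=p_perm,
                    n_permutations=n_perm or 0, seed=seed)


# ---------------------------------------------------------------------------
# t tests

@dataclass
class TestResult:
    """Two-group comparison of one variable."""

    variable: str
    mean_x: float
    mean_y: float
    difference: float  # mean_x − mean_y
    statistic: float
    df: float
    p_value: float
    direction: str  # "+", "-", or "ns" at alpha
    alpha: float = 0.05
    p_adjusted: float | None = None


_T_MODES = ("welch", "student", "paired")


def t_test(x, y, mode: str = "welch", variable: str = "",
           alpha: float = 0.05) -> TestResult:
    """Two-sample or paired t test; difference is mean(x) − mean(y)."""
    if mode not in _T_MODES:
        raise ValueError(f"mode must be one of {_T_MODES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.shape != y.shape:
            raise ValueError("paired mode requires matched units of equal length")
        if x.shape[0] < 2:
            raise ValueError("paired mode requires at least 2 pairs")
        d = x - y
        if np.ptp(d) == 0 and d[0] != 0:
            raise ValueError("degenerate paired data: zero variance of non-zero differences")
    else:
        if x.shape[0] < 2 or y.shape[0] < 2:
            raise ValueError("need at least 2 units per group")

    mean_x, mean_y = float(x.mean()), float(y.mean())
    diff = mean_x - mean_y

    if np.ptp(x) == 0 and np.ptp(y) == 0 and mean_x == mean_y:
        stat, df, p = 0.0, float(x.shape[0] + y.shape[0] - 2), 1.0
    elif mode == "paired":
        res = sps.ttest_rel(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(x.shape[0] - 1)
    else:
        res = sps.ttest_ind(x, y, equal_var=(mode == "student"))
        stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    direction = "ns" if p >= alpha else ("+" if diff > 0 else "-")
    return TestResult(variable=variable, mean_x=mean_x, mean_y=mean_y,
                      difference=diff, statistic=stat, df=df, p_value=p,
                      direction=direction, alpha=alpha)
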