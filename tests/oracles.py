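"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic DP, exhaustive
enumeration, all-combinations search) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def sw_score_affine(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman score, full O(nm) affine-gap DP (Gotoh), BLOSUM62.

    A gap of length g costs gap_open + g * gap_extend (BLAST convention).
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


_MOTIFS = (r"D[TS]G", r"Y", r"[AFILMV][AFILMV]G", r"D[TS]G", r"[AFILMV][AFILMV]G")


def hallmark_pass_exhaustive(sequence: str) -> bool:
    """All-positions ordered search: does ANY non-overlapping ordered
    combination of the five motif matches exist?"""
    seq = sequence.upper()
    occurrences = []
    for pat in _MOTIFS:
        spans = [(m.start(1), m.end(1))
                 for m in re.finditer(f"(?=({pat}))", seq)]
        if not spans:
            return False
        occurrences.append(spans)

    def search(level: int, min_start: int) -> bool:
        if level == len(occurrences):
            return True
        for start, end in occurrences[level]:
            if start >= min_start and search(level + 1, end):
                return True
        return False

    return search(0, 0)


def anosim_r_naive(dist: np.ndarray, labels) -> float:
    """ANOSIM R via explicit loops and a hand mid-rank assignment."""
    labels = list(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = [dist[i, j] for i, j in pairs]
    order = sorted(range(len(d)), key=lambda k: d[k])
    ranks = [0.0] * len(d)
    k = 0
    while k < len(order):
        k2 = k
        while k2 + 1 < len(order) and d[order[k2 + 1]] == d[order[k]]:
            k2 += 1
        mid = (k + k2) / 2 + 1
        for t in range(k, k2 + 1):
            ranks[order[t]] = mid
        k = k2 + 1
    between = [ranks[t] for t, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    within = [ranks[t] for t, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    m_half = len(pairs) / 2
    return (sum(between) / len(between) - sum(within) / len(within)) / m_half


def anosim_p_exhaustive(dist: np.ndarray, labels) -> float:
    """Exact permutation P over all distinct two-group label assignments."""
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    assert len(uniq) == 2
    n1 = int((labels == uniq[0]).sum())
    r_obs = anosim_r_naive(dist, labels)
    n_ge = total = 0
    for combo in itertools.combinations(range(n), n1):
        lab = np.full(n, uniq[1], dtype=object)
        lab[list(combo)] = uniq[0]
        total += 1
        if anosim_r_naive(dist, lab) >= r_obs - 1e-12:
            n_ge += 1
    return n_ge / total


def kw_h_rank_sum(groups) -> float:
    """Tie-corrected H computed via a hand rank-sum formula."""
    values = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        sz = len(g)
        h += ranks[start:start + sz].sum() ** 2 / sz
        start += sz
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    c = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / c if c > 0 else 0.0


def kw_p_exhaustive(x, y) -> float:
    """Exact permutation P of the two-group Kruskal-Wallis H."""
    x, y = list(x), list(y)
    pool = x + y
    h_obs = kw_h_rank_sum([x, y])
    n_ge = total = 0
    for combo in itertools.combinations(range(len(pool)), len(x)):
        g1 = [pool[i] for i in combo]
        g2 = [pool[i] for i in range(len(pool)) if i not in combo]
        total += 1
        if kw_h_rank_sum([g1, g2]) >= h_obs - 1e-9:
            n_ge += 1
    return n_ge / total
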