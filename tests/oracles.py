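"""Independent brute-force oracles used to cross-check the test battery.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: the Wilcoxon oracle enumerates
all 2^n sign assignments, the McNemar oracle enumerates all 2^n
discordant-direction assignments, and the Kruskal-Wallis oracle walks
every permutation of the pooled sample.
"""

from itertools import permutations, product

import numpy as np
from scipy.stats import rankdata


def wilcoxon_exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by exhaustive sign enumeration.

    ``diffs`` must be non-zero and tie-free in magnitude.
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) over the 2^n equally
    likely sign assignments.
    """
    diffs = np.asarray(diffs, dtype=float)
    assert np.all(diffs != 0)
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([True, False], repeat=len(diffs))
    ])
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def mcnemar_exact_p(b: int, c: int) -> float:
    """Two-sided exact McNemar p by enumerating discordant directions.

    Under the null each of the n = b + c discordant pairs flips either
    way with probability 1/2; the two-sided p sums the probability of
    every outcome no more likely than the observed split.
    """
    n = b + c
    assert n >= 1
    counts = np.zeros(n + 1)
    for directions in product([0, 1], repeat=n):
        counts[sum(directions)] += 1
    pmf = counts / 2**n
    obs = pmf[b]
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


def _h_stat(pooled: np.ndarray, sizes: list[int]) -> float:
    n = len(pooled)
    ranks = rankdata(pooled)
    h, start = 0.0, 0
    for size in sizes:
        h += ranks[start : start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, cnt = np.unique(pooled, return_counts=True)
    tie = 1 - (cnt**3 - cnt).sum() / (n**3 - n)
    return 0.0 if tie == 0 else h / tie


def kruskal_exhaustive_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p for the Kruskal-Wallis H statistic.

    Enumerates every ordering of the pooled sample (feasible for total
    n <= 7) and reports P(H* >= H_obs).
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = _h_stat(pooled, sizes)
    count = total = 0
    for perm in permutations(pooled):
        total += 1
        if _h_stat(np.array(perm), sizes) >= h_obs - 1e-12:
            count += 1
    return count / total


def percentiles_linear(values, qs=(25, 50, 75)) -> tuple[float, ...]:
    """Sort-based linear-interpolation order statistics (manual)."""
    x = sorted(float(v) for v in values)
    n = len(x)
    out = []
    for q in qs:
        pos = (q / 100) * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        frac = pos - lo
        out.append(x[lo] * (1 - frac) + x[hi] * frac)
    return tuple(out)
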