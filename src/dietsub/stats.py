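"""The scenario-comparison test battery and pairwise significance letters.

Two-sided tests throughout, alpha = 0.05 by default:

* Wilcoxon signed-rank for paired intakes before/after a scenario.
  Zero differences are discarded before ranking by default (the classic
  convention; most of the cohort are non-consumers whose differences are
  exactly zero), with a Pratt option.  The exact null distribution is
  used for <= 25 effective pairs without ties, otherwise the normal
  approximation with tie correction.
* McNemar for paired inadequacy flags, using only discordant pairs:
  exact binomial below 25 discordant pairs, continuity-corrected
  chi-square otherwise.
* Kruskal-Wallis H (tie-corrected) across model groups, with a seeded
  permutation fallback for small samples.
* Pearson chi-square without continuity correction for r x c
  consumption-by-age tables.

Degenerate no-signal inputs (all differences zero, no discordant pairs,
identical groups) return p = 1 with a method note instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PairwiseLetters",
    "wilcoxon_signed_rank",
    "mcnemar",
    "kruskal_wallis",
    "chi_square_independence",
    "annotate",
    "COMPARISON_ROWS",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_effective: int
    method_note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "discard",
    exact_threshold: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``zero_method`` is "discard" (drop zero differences before ranking)
    or "pratt".  With "discard", the exact null distribution is used when
    the number of non-zero differences is <= ``exact_threshold`` and
    their magnitudes are tie-free; otherwise (and always under "pratt")
    the normal approximation with tie correction is used, without
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equal-length 1-D samples of size >= 1")
    d = y - x
    nonzero = d[d != 0]
    n_eff = len(nonzero)
    if n_eff == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0, "all differences zero")
    if zero_method == "discard":
        ties = len(np.unique(np.abs(nonzero))) < n_eff
        if n_eff <= exact_threshold and not ties:
            res = sps.wilcoxon(nonzero, zero_method="wilcox", method="exact")
            note = "exact"
        else:
            res = sps.wilcoxon(
                nonzero, zero_method="wilcox", method="approx", correction=False
            )
            note = "normal approximation, tie-corrected" if ties else "normal approximation"
    elif zero_method == "pratt":
        res = sps.wilcoxon(d, zero_method="pratt", method="approx", correction=False)
        note = "pratt zeros, normal approximation"
    else:
        raise ValueError("zero_method must be 'discard' or 'pratt'")
    return TestResult(
        "wilcoxon_signed_rank",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        n_eff,
        note,
    )


def mcnemar(
    before: Sequence[bool],
    after: Sequence[bool],
    exact_threshold: int = 25,
) -> TestResult:
    """Two-sided McNemar test on paired binary flags.

    Only discordant pairs enter the statistic: b (True -> False) and
    c (False -> True).  Exact binomial when b + c < ``exact_threshold``,
    continuity-corrected chi-square (1 df) otherwise.
    """
    before = np.asarray(before, dtype=bool)
    after = np.asarray(after, dtype=bool)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D flag arrays")
    b = int(np.sum(before & ~after))
    c = int(np.sum(~before & after))
    n_disc = b + c
    if n_disc == 0:
        return TestResult("mcnemar", 0.0, 1.0, 0, "no discordant pairs")
    if n_disc < exact_threshold:
        p = sps.binomtest(b, n_disc, 0.5).pvalue
        return TestResult("mcnemar", float(min(b, c)), float(min(p, 1.0)), n_disc, "exact binomial")
    stat = (abs(b - c) - 1) ** 2 / n_disc
    p = sps.chi2.sf(stat, df=1)
    return TestResult(
        "mcnemar", float(stat), float(p), n_disc, "continuity-corrected chi-square"
    )


def _h_statistic(pooled: np.ndarray, sizes: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled values split by sizes."""
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for size in sizes:
        r = ranks[start : start + size]
        h += r.sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_term == 0:
        return 0.0
    return h / tie_term


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: str = "asymptotic",
    n_resamples: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    ``method`` is "asymptotic" (chi-square with k-1 df, tie-corrected H)
    or "permutation" (seeded Monte-Carlo resampling of group labels,
    p = (1 + #{H* >= H}) / (1 + n_resamples)).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    sizes = np.array([len(a) for a in arrays])
    if len(pooled) < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, len(pooled), "all values identical")
    h_obs = _h_statistic(pooled, sizes)
    if method == "asymptotic":
        stat, p = sps.kruskal(*arrays)
        return TestResult(
            "kruskal_wallis", float(stat), float(p), len(pooled), f"chi-square, {len(sizes) - 1} df"
        )
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        work = pooled.copy()
        for _ in range(n_resamples):
            rng.shuffle(work)
            if _h_statistic(work, sizes) >= h_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_resamples)
        return TestResult(
            "kruskal_wallis", float(h_obs), float(p), len(pooled),
            f"permutation, {n_resamples} resamples",
        )
    raise ValueError("method must be 'asymptotic' or 'permutation'")


def chi_square_independence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction (the survey use is a 2 x 3 table, df = 2).
    Emits a warning when any expected count is below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column marginal")
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=False)
    note = f"Pearson, {dof} df"
    if expected.min() < 5:
        warnings.warn(
            f"minimum expected count {expected.min():.2f} < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
        note += f", min expected {expected.min():.2f} < 5"
    return TestResult("chi_square", float(chi2), float(p), int(t.sum()), note)


# Which report row carries each comparison letter: a/b/c are model vs
# baseline, d/e/f are between-model comparisons.
COMPARISON_ROWS: dict[str, str] = {
    "a": "model1",
    "b": "model2",
    "c": "model3",
    "d": "model2",
    "e": "model3",
    "f": "model3",
}


@dataclass(frozen=True)
class PairwiseLetters:
    """Rendered significance letters for the six scenario comparisons.

    ``p_values`` maps letters a-f to p-values (``None`` = not run); a
    letter is shown on its row iff p < alpha (strict).  Baseline rows
    never carry letters.
    """

    p_values: Mapping[str, float | None]
    alpha: float = ALPHA_DEFAULT

    def letters(self, row: str) -> str:
        if row == "before":
            return ""
        return "".join(
            letter
            for letter in "abcdef"
            if COMPARISON_ROWS[letter] == row
            and self.p_values.get(letter) is not None
            and self.p_values[letter] < self.alpha
        )

    def as_dict(self) -> dict[str, str]:
        return {row: self.letters(row) for row in ("before", "model1", "model2", "model3")}


def annotate(p_values: Mapping[str, float | None], alpha: float = ALPHA_DEFAULT) -> PairwiseLetters:
    """Build the a-f letter annotation from six comparison p-values."""
    unknown = set(p_values) - set("abcdef")
    if unknown:
        raise ValueError(f"unknown comparison keys: {sorted(unknown)}")
    return PairwiseLetters({k: p_values.get(k) for k in "abcdef"}, alpha)
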