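"""Nonparametric statistics battery.

All group-level comparisons in the pipeline go through the four tests here:
paired / one-sample Wilcoxon signed-rank, Mann-Whitney U, Spearman's rho and
Fisher's exact test. Two-sided p-values throughout, significance conventionally
at p < 0.05.

Small samples get exact nulls: the signed-rank null is enumerated by a
shift-sum dynamic program over (possibly tied, half-integer) ranks for
n <= 25; Mann-Whitney uses the exact U distribution for min(n) <= 8 without
ties; Spearman's p is an exact permutation tail for n <= 10; Fisher's p is the
usual two-sided hypergeometric tail-mass sum. Larger samples fall back on the
standard normal/t approximations with tie corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import sqrt
from typing import Optional

import numpy as np
from scipy import stats as sps

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 8
SPEARMAN_EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``p_value`` is NaN and ``note`` explains why when the test is not
    computable (e.g. all paired differences are zero).
    """

    name: str
    statistic: float
    p_value: float
    n: int
    effect: dict = field(default_factory=dict)
    note: Optional[str] = None

    @property
    def computable(self) -> bool:
        return self.note is None

    def __str__(self) -> str:
        if not self.computable:
            return f"{self.name}: not computable ({self.note})"
        eff = ", ".join(f"{k}={v:.4g}" for k, v in self.effect.items())
        return f"{self.name}: stat={self.statistic:.4g}, p={self.p_value:.4g}, n={self.n} ({eff})"


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _signed_rank_null(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Exact null pmf of the positive-rank sum, on the doubled-rank grid.

    Ranks are doubled so tied (average, half-integer) ranks become integers;
    entry k of the returned array is P(2 * W+ == k) under random signs.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def _wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
    pmf = _signed_rank_null(doubled)
    k = int(round(2 * w_plus))
    p_low = pmf[: k + 1].sum()
    p_high = pmf[k:].sum()
    return w_plus, min(1.0, 2.0 * min(p_low, p_high))


def _wilcoxon_approx_p(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    x, y=None, mu: float = 0.0, name: str = "wilcoxon_signed_rank"
) -> TestResult:
    """Paired (x vs y) or one-sample (x vs theoretical ``mu``) signed-rank test.

    Zero differences are dropped (the classic Wilcoxon convention). Exact
    enumeration null for n <= 25 nonzero differences, normal approximation
    with tie correction beyond.
    """
    x = np.asarray(x, dtype=float)
    diffs = x - (np.asarray(y, dtype=float) if y is not None else mu)
    diffs = diffs[~np.isnan(diffs)]
    n_total = diffs.size
    diffs = diffs[diffs != 0]
    if diffs.size < 2:
        return TestResult(name, float("nan"), float("nan"), n_total,
                          note="fewer than 2 nonzero differences")
    if diffs.size <= WILCOXON_EXACT_MAX_N:
        stat, p = _wilcoxon_exact_p(diffs)
    else:
        stat, p = _wilcoxon_approx_p(diffs)
    return TestResult(
        name, float(stat), float(p), n_total,
        effect={"median_difference": float(np.median(diffs)), "n_nonzero": diffs.size},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(a, b, name: str = "mann_whitney_u") -> TestResult:
    """Two-sided Mann-Whitney U; exact null when min(nA, nB) <= 8 and untied."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return TestResult(name, float("nan"), float("nan"), a.size + b.size,
                          note="empty group")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= MANNWHITNEY_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        name, float(res.statistic), float(res.pvalue), a.size + b.size,
        effect={
            "median_difference": float(np.median(a) - np.median(b)),
            "n_a": a.size, "n_b": b.size,
        },
    )


# ---------------------------------------------------------------------------
# Spearman's rho
# ---------------------------------------------------------------------------

def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho: float) -> float:
    """Exact permutation two-sided p: share of pairings with |rho| >= |observed|."""
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = sqrt((xc**2).sum() * (yc**2).sum())
    perms = np.array(list(itertools.permutations(yc)))
    rhos = perms @ xc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_rho(x, y, name: str = "spearman_rho") -> TestResult:
    """Spearman rank correlation with average ranks on ties.

    Exact permutation p for n <= 10, otherwise the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return TestResult(name, float("nan"), float("nan"), n, note="n < 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(name, float("nan"), float("nan"), n, note="constant input")
    rho, p_approx = sps.spearmanr(x, y)
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(sps.rankdata(x), sps.rankdata(y), float(rho))
    else:
        p = float(p_approx)
    return TestResult(name, float(rho), p, n, effect={"rho": float(rho)})


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table, name: str = "fisher_exact") -> TestResult:
    """Two-sided Fisher exact p by hypergeometric tail-mass summation."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be a nonnegative 2x2 integer matrix")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(name, float("nan"), float("nan"), int(table.sum()),
                          note="empty margin")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(
        name, float(odds), float(p), int(table.sum()),
        effect={"odds_ratio": float(odds)},
    )
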