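"""Nonparametric battery against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from littkinetics import (
    fisher_exact,
    mann_whitney_u,
    spearman_rho,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def wilcoxon_p_by_enumeration(diffs):
    """Two-sided exact signed-rank p over all 2^n sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = ranks.size
    sums = np.array([
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_low = np.mean(sums <= w_obs + 1e-12)
    p_high = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def mwu_p_by_enumeration(a, b):
    """Two-sided exact Mann-Whitney p over all group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), na):
        r = ranks[list(idx)].sum() - na * (na + 1) / 2
        us.append(r)
    us = np.array(us)
    mid = na * (n - na) / 2
    return float(np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12))


def spearman_p_by_enumeration(x, y):
    rho_obs, _ = sps.spearmanr(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rhos = []
    for perm in itertools.permutations(ry):
        r, _ = sps.pearsonr(rx, np.array(perm))
        rhos.append(r)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "diffs",
    [
        [1, 2, 3, 4, 5, 6],
        [-1, 1],
        [-1, 2, -3, 4, 5],
        [1.5, 1.5, -2.0, 3.0, -0.5, 0.5, 2.5],  # ties in |d|
        [2, -2, 2, -2, 1],
    ],
)
def test_wilcoxon_exact_matches_enumeration(diffs):
    res = wilcoxon_signed_rank(diffs)
    assert res.p_value == pytest.approx(wilcoxon_p_by_enumeration(diffs), abs=1e-12)


def test_wilcoxon_all_positive_n6_exact_value():
    # 2/64 sign assignments reach the extreme positive-rank sum
    assert wilcoxon_signed_rank([1, 2, 3, 4, 5, 6]).p_value == pytest.approx(2 / 64)


def test_wilcoxon_symmetric_pair_is_uninformative():
    assert wilcoxon_signed_rank([-1, 1]).p_value == 1.0


def test_wilcoxon_zeros_dropped_and_flagged():
    res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
    assert not res.computable
    res = wilcoxon_signed_rank([5, 4, 3], [5, 4, 3])
    assert not res.computable


def test_wilcoxon_paired_and_one_sample_agree():
    x = np.array([3.0, 5.0, 7.0, 2.0, 9.0])
    y = np.array([1.0, 6.0, 3.0, 2.5, 4.0])
    assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
        wilcoxon_signed_rank(x - y).p_value
    )


def test_wilcoxon_large_n_approximation_close_to_exact_boundary():
    rng = np.random.default_rng(0)
    d = rng.normal(0.3, 1.0, 26)   # just above the exact-null cutoff
    res = wilcoxon_signed_rank(d)
    exact_like = sps.wilcoxon(d, method="approx").pvalue
    assert res.p_value == pytest.approx(exact_like, abs=0.02)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwu_separated_groups_exact_value():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.p_value == pytest.approx(0.1)


@pytest.mark.parametrize(
    "a,b",
    [
        ([1.2, 3.4, 2.2], [0.5, 4.4, 5.1, 2.8]),
        ([10, 20], [5, 15, 25, 35, 45]),
    ],
)
def test_mwu_exact_matches_enumeration(a, b):
    res = mann_whitney_u(a, b)
    assert res.p_value == pytest.approx(mwu_p_by_enumeration(a, b), abs=1e-12)


def test_mwu_identical_groups_uninformative():
    res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0, abs=0.05)


def test_mwu_ordering_invariance():
    a = [3.0, 1.0, 4.0, 1.5]
    b = [9.0, 2.6, 5.0]
    assert mann_whitney_u(a, b).p_value == mann_whitney_u(a[::-1], b[::-1]).p_value


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_correlations():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman_rho(x, x).statistic == pytest.approx(1.0)
    assert spearman_rho(x, [-v for v in x]).statistic == pytest.approx(-1.0)


def test_spearman_rank_formula_example():
    # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
    res = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.statistic == pytest.approx(0.8)


@pytest.mark.parametrize("n", [4, 5, 6])
def test_spearman_exact_p_matches_enumeration(n):
    rng = np.random.default_rng(n)
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    res = spearman_rho(x, y)
    assert res.p_value == pytest.approx(spearman_p_by_enumeration(x, y), abs=1e-12)


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman_rho(x, y)
    warped = spearman_rho(np.exp(x), y**3)
    assert warped.statistic == pytest.approx(base.statistic)
    assert warped.p_value == pytest.approx(base.p_value)


def test_spearman_constant_input_flagged():
    assert not spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]).computable


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_fisher_perfect_diagonal():
    # hypergeometric: only the two extreme tables are as unlikely -> 2/C(10,5)
    res = fisher_exact([[5, 0], [0, 5]])
    assert res.p_value == pytest.approx(2 / comb(10, 5))


def test_fisher_balanced_table_uninformative():
    assert fisher_exact([[1, 1], [1, 1]]).p_value == 1.0


def test_fisher_empty_margin_flagged():
    assert not fisher_exact([[0, 0], [3, 4]]).computable


def test_fisher_matches_hypergeometric_tail_sum():
    table = np.array([[6, 5], [0, 17]])
    res = fisher_exact(table)
    # tail-mass summation over all tables with the observed margins
    row, col = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    probs = [sps.hypergeom.pmf(k, n, row[0], col[0])
             for k in range(max(0, row[0] + col[0] - n), min(row[0], col[0]) + 1)]
    p_obs = sps.hypergeom.pmf(table[0, 0], n, row[0], col[0])
    expected = sum(p for p in probs if p <= p_obs + 1e-12)
    assert res.p_value == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# type-I calibration (seeded)
# ---------------------------------------------------------------------------

def test_type_one_error_calibration_at_nominal_alpha():
    """Simulated size of each test stays near 0.05 under its null at n = 20."""
    rng = np.random.default_rng(2024)
    reps = 10_000
    rejections = {"wilcoxon": 0, "mwu": 0, "spearman": 0}
    for _ in range(reps):
        d = rng.normal(size=20)
        if wilcoxon_signed_rank(d).p_value < 0.05:
            rejections["wilcoxon"] += 1
        a, b = rng.normal(size=20), rng.normal(size=20)
        if mann_whitney_u(a, b).p_value < 0.05:
            rejections["mwu"] += 1
        if spearman_rho(a, b).p_value < 0.05:
            rejections["spearman"] += 1
    for name, count in rejections.items():
        assert 0.03 <= count / reps <= 0.07, f"{name} size {count / reps}"
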