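"""Bi-exponential volume models: identities, fitting, derived metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit

import littkinetics as lk
from littkinetics.errors import InsufficientDataError, NormalizationError
from littkinetics.kinetics import RATE_BOUND

from conftest import make_trajectory

DAYS = np.array([0.0, 15.0, 30.0, 60.0, 120.0, 200.0, 365.0])

admissible_alpha = st.floats(0.0, 1.0)
admissible_rate = st.floats(0.0, RATE_BOUND)


# ---------------------------------------------------------------------------
# curve identities
# ---------------------------------------------------------------------------

@given(admissible_alpha, admissible_rate, admissible_rate)
def test_decay_growth_is_100_percent_at_day0(alpha, b1, b2):
    assert lk.decay_growth_curve(0.0, alpha, b1, b2) == pytest.approx(100.0, abs=1e-12)


@given(admissible_alpha, admissible_rate, admissible_rate,
       st.floats(0.0, 99.0))
def test_decay_decay_is_100_percent_at_day0(alpha, b1, b2, plateau):
    assert lk.decay_decay_curve(0.0, alpha, b1, b2, plateau) == pytest.approx(
        100.0, abs=1e-12
    )


def test_rate_bound_implies_subweek_half_life():
    # the 0-0.1/day bound excludes half-lives and doubling times under 7 days
    assert np.log(2) / RATE_BOUND == pytest.approx(6.93, abs=0.005)
    assert np.log(2) / RATE_BOUND < 7.0


# ---------------------------------------------------------------------------
# closed-form time to growth
# ---------------------------------------------------------------------------

def test_ttg_closed_form_example():
    ttg, flag = lk.time_to_growth_closed_form(0.8, 0.05, 0.02)
    assert flag == "regrowth"
    assert ttg == pytest.approx(np.log(10) / 0.07, abs=1e-9)  # ~32.89 d


def test_ttg_boundary_regimes():
    assert lk.time_to_growth_closed_form(1.0, 0.05, 0.02) == (1095.0, "no_regrowth")
    assert lk.time_to_growth_closed_form(0.5, 0.05, 0.0) == (1095.0, "no_regrowth")
    assert lk.time_to_growth_closed_form(0.0, 0.05, 0.02) == (0.0, "immediate_regrowth")
    # alpha*beta1 < (1-alpha)*beta2 puts the stationary point at t < 0
    ttg, flag = lk.time_to_growth_closed_form(0.1, 0.01, 0.09)
    assert (ttg, flag) == (0.0, "immediate_regrowth")


def test_ttg_closed_form_agrees_with_dense_grid_argmin():
    """Analytic argmin vs brute-force grid search over random admissible draws."""
    rng = np.random.default_rng(11)
    grid = np.arange(0.0, 1095.0 + 0.05, 0.05)
    for _ in range(300):
        alpha = rng.uniform(0.05, 0.95)
        b1 = rng.uniform(1e-3, RATE_BOUND)
        b2 = rng.uniform(1e-3, RATE_BOUND)
        ttg, _ = lk.time_to_growth_closed_form(alpha, b1, b2)
        brute = grid[np.argmin(lk.decay_growth_curve(grid, alpha, b1, b2))]
        assert abs(ttg - brute) <= 0.1


def test_decay_growth_monotone_around_minimum():
    alpha, b1, b2 = 0.7, 0.04, 0.015
    ttg, _ = lk.time_to_growth_closed_form(alpha, b1, b2)
    before = np.linspace(0, ttg - 1e-6, 200)
    after = np.linspace(ttg + 1e-6, 1095, 200)
    v_before = lk.decay_growth_curve(before, alpha, b1, b2)
    v_after = lk.decay_growth_curve(after, alpha, b1, b2)
    assert np.all(np.diff(v_before) < 0)
    assert np.all(np.diff(v_after) > 0)


# ---------------------------------------------------------------------------
# percent-series construction
# ---------------------------------------------------------------------------

def test_percent_series_normalizes_to_post_litt():
    traj = make_trajectory({-7: 2.0, 0: 3.5, 30: 1.75})
    days, pct = lk.to_percent_series(traj)
    assert days.tolist() == [0.0, 30.0]
    assert pct.tolist() == [100.0, 50.0]


def test_percent_series_rejects_zero_post_volume():
    traj = make_trajectory({-7: 2.0, 0: 0.0, 30: 1.0})
    with pytest.raises(NormalizationError):
        lk.to_percent_series(traj)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_decay_growth_recovers_noise_free_parameters():
    truth = dict(alpha=0.8, beta1=0.05, beta2=0.02)
    days = np.array([0.0, 15.0, 30.0, 60.0, 120.0])
    pct = lk.decay_growth_curve(days, **truth)
    res = lk.fit_decay_growth(days, pct)
    assert res.params.alpha == pytest.approx(truth["alpha"], abs=1e-4)
    assert res.params.beta1 == pytest.approx(truth["beta1"], abs=1e-4)
    assert res.params.beta2 == pytest.approx(truth["beta2"], abs=1e-4)
    assert round(res.rsquared, 2) == 1.0


def test_fit_decay_growth_pure_decay_is_monotone_on_span():
    days = np.array([0.0, 20.0, 60.0, 150.0])
    pct = lk.decay_growth_curve(days, 1.0, 0.01, 0.0)
    res = lk.fit_decay_growth(days, pct)
    tt = np.linspace(0, 150, 300)
    assert np.all(np.diff(res.predict(tt)) <= 1e-9)


def test_fit_decay_decay_recovers_noise_free_curve():
    """The curve (and hence metrics) is recovered essentially exactly.

    Individual coefficients of a bi-exponential are only weakly identifiable
    from a dozen points, so recovery is asserted at the curve level.
    """
    truth = dict(alpha=0.6, beta1=0.08, beta2=0.008, plateau=10.0)
    days = np.array([0.0, 15.0, 33.0, 63.0, 95.0, 130.0, 180.0, 270.0, 365.0,
                     550.0, 730.0, 1000.0])
    pct = lk.decay_decay_curve(days, **truth)
    res = lk.fit_decay_decay(days, pct)
    tt = np.linspace(0.0, 1095.0, 500)
    true_curve = lk.decay_decay_curve(tt, **truth)
    assert np.max(np.abs(res.predict(tt) - true_curve)) < 1e-2
    assert round(res.rsquared, 2) == 1.0
    assert res.params.beta1 >= res.params.beta2
    m = res.metrics()
    true_m = lk.derive_metrics(
        lk.BiExpParams("decay_decay", **truth)
    )
    assert m.pseudo_half_life == pytest.approx(true_m.pseudo_half_life, abs=0.1)
    assert m.plateau == pytest.approx(truth["plateau"], abs=0.1)


def test_fit_decay_decay_matches_mono_exponential_limit():
    """With beta1 = beta2 truth, the bi-exponential fit is as good as a
    mono-exponential oracle fit (the model collapses gracefully)."""
    days = np.array([0.0, 30.0, 60.0, 120.0, 240.0, 480.0])
    pct = lk.decay_decay_curve(days, alpha=0.4, beta1=0.01, beta2=0.01, plateau=0.0)
    res = lk.fit_decay_decay(days, pct)

    def mono(t, rate):
        return 100.0 * np.exp(-rate * t)

    (rate_hat,), _ = curve_fit(mono, days, pct, p0=[0.005], bounds=(0.0, 0.1))
    sse_mono = float(np.sum((mono(days, rate_hat) - pct) ** 2))
    assert res.sse <= sse_mono + 1e-9
    assert res.sse < 1e-9


def test_mono_exponential_pseudo_half_life_closed_form():
    days = np.array([0.0, 50.0, 100.0, 200.0, 400.0])
    pct = lk.decay_decay_curve(days, alpha=1.0, beta1=0.01, beta2=0.0, plateau=0.0)
    res = lk.fit_decay_decay(days, pct)
    assert res.metrics().pseudo_half_life == pytest.approx(np.log(2) / 0.01, abs=0.05)


def test_fit_requires_minimum_timepoints():
    with pytest.raises(InsufficientDataError):
        lk.fit_decay_growth([0.0, 30.0], [100.0, 60.0])
    with pytest.raises(InsufficientDataError):
        lk.fit_decay_decay([0.0, 30.0, 90.0], [100.0, 60.0, 40.0])
    with pytest.raises(InsufficientDataError):
        lk.fit_decay_growth([10.0, 30.0, 90.0], [100.0, 60.0, 80.0])  # no day 0


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def test_metrics_no_regrowth_flag_for_pure_decay():
    params = lk.BiExpParams("decay_growth", alpha=1.0, beta1=0.02, beta2=0.0)
    m = lk.derive_metrics(params)
    assert m.ttg_flag == "no_regrowth"
    assert m.time_to_growth == 1095.0


def test_metrics_high_plateau_leaves_half_life_undefined():
    params = lk.BiExpParams("decay_decay", alpha=0.5, beta1=0.05, beta2=0.01,
                            plateau=60.0)
    m = lk.derive_metrics(params)
    assert not m.pseudo_half_life_defined
    assert m.depth_of_shrinkage <= 40.0


def test_metrics_depth_of_shrinkage_from_fitted_minimum():
    params = lk.BiExpParams("decay_growth", alpha=0.8, beta1=0.05, beta2=0.02)
    m = lk.derive_metrics(params)
    v_min = float(params.predict(m.time_to_growth))
    assert m.depth_of_shrinkage == pytest.approx(100.0 - v_min)
    assert 0.0 <= m.depth_of_shrinkage <= 100.0


def test_results_summary_mentions_key_quantities(small_cohort_fits):
    fits, labels, _ = small_cohort_fits
    some_fit = next(iter(fits.values()))
    text = some_fit.summary()
    assert "alpha" in text and "R^2" in text
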