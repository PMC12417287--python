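"""Lesion-specific bi-exponential volume kinetics.

CE volume after LITT is expressed as a percentage of the immediate post-LITT
scan (day 0 = 100%) and modeled per lesion with one of two bi-exponential
forms:

* progressors (decay-growth) ::

      V(t) = beta0 * [alpha * exp(-beta1 t) + (1 - alpha) * exp(+beta2 t)]

  a decay component for the resolution of the transient heat-induced
  blood-brain-barrier opening plus an exponential regrowth component;

* responders (decay-decay) ::

      V(t) = plateau + (beta0 - plateau)
             * [alpha * exp(-beta1 t) + (1 - alpha) * exp(-beta2 t)]

  a steeper early decay plus a milder late decay toward a residual-scar
  plateau, with beta1 >= beta2 enforced by the reparameterization
  beta2 = beta1 * s, s in [0, 1].

In both forms beta0 is fixed at 100 (the curve passes through 100% at day 0
exactly) and the rate coefficients are bounded to [0, 0.1] / day: a rate above
0.1 would imply a half-life or doubling time under 7 days
(ln 2 / 0.1 ~= 6.93 days), which is biologically implausible here.

Fitting is bounded nonlinear least squares with a deterministic multi-start
grid; the API follows the statsmodels model/results idiom:

>>> model = DecayGrowthModel(days, percents)
>>> res = model.fit()
>>> res.params.beta1, res.rsquared, res.metrics().time_to_growth
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .cohort import LesionTrajectory
from .errors import FitFailureError, InsufficientDataError, NormalizationError

BETA0 = 100.0
RATE_BOUND = 0.1           # per day; ln2/0.1 ~= 6.93 d half-life floor
DEFAULT_HORIZON = 1095     # days (~3 y of follow-up) for metric extraction

ALPHA_STARTS = np.arange(0.1, 0.95, 0.1)
RATE_STARTS = np.array([0.001, 0.005, 0.01, 0.05, 0.1])
RATIO_STARTS = np.array([0.05, 0.5, 1.0])

NO_REGROWTH = "no_regrowth"
IMMEDIATE_REGROWTH = "immediate_regrowth"
REGROWTH = "regrowth"


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def decay_growth_curve(t, alpha, beta1, beta2, beta0=BETA0):
    """Eq. for progressors: decay plus exponential regrowth; 100% at t = 0."""
    t = np.asarray(t, dtype=float)
    return beta0 * (alpha * np.exp(-beta1 * t) + (1.0 - alpha) * np.exp(beta2 * t))


def decay_decay_curve(t, alpha, beta1, beta2, plateau, beta0=BETA0):
    """Eq. for responders: two decays toward a plateau; 100% at t = 0."""
    t = np.asarray(t, dtype=float)
    return plateau + (beta0 - plateau) * (
        alpha * np.exp(-beta1 * t) + (1.0 - alpha) * np.exp(-beta2 * t)
    )


def time_to_growth_closed_form(
    alpha: float, beta1: float, beta2: float, horizon: float = DEFAULT_HORIZON
) -> tuple[float, str]:
    """Argmin of the decay-growth curve on [0, horizon], with a regime flag.

    The interior minimum solves V'(t*) = 0:
    t* = ln(alpha*beta1 / ((1-alpha)*beta2)) / (beta1 + beta2).
    alpha = 1 or beta2 = 0 gives a nonincreasing curve (no regrowth within any
    horizon); alpha = 0, beta1 = 0 or t* <= 0 gives immediate regrowth.
    """
    if alpha >= 1.0 or beta2 <= 0.0:
        return float(horizon), NO_REGROWTH
    if alpha <= 0.0 or beta1 <= 0.0:
        return 0.0, IMMEDIATE_REGROWTH
    t_star = np.log(alpha * beta1 / ((1.0 - alpha) * beta2)) / (beta1 + beta2)
    if t_star <= 0.0:
        return 0.0, IMMEDIATE_REGROWTH
    if t_star >= horizon:
        return float(horizon), NO_REGROWTH
    return float(t_star), REGROWTH


# ---------------------------------------------------------------------------
# parameters / metrics containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiExpParams:
    """Coefficients of one fitted (or ground-truth) bi-exponential curve."""

    model: str                  # "decay_growth" | "decay_decay"
    alpha: float
    beta1: float
    beta2: float
    plateau: Optional[float] = None   # decay_decay only
    beta0: float = BETA0

    def __post_init__(self):
        if self.model not in ("decay_growth", "decay_decay"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for b in (self.beta1, self.beta2):
            if not 0.0 <= b <= RATE_BOUND:
                raise ValueError(f"rate coefficients must lie in [0, {RATE_BOUND}]")
        if self.model == "decay_decay":
            if self.plateau is None:
                raise ValueError("decay_decay requires a plateau")
            if not 0.0 <= self.plateau < self.beta0:
                raise ValueError("plateau must lie in [0, 100)")
            if self.beta1 < self.beta2 - 1e-12:
                raise ValueError("decay_decay requires beta1 >= beta2")

    def predict(self, t):
        if self.model == "decay_growth":
            return decay_growth_curve(t, self.alpha, self.beta1, self.beta2, self.beta0)
        return decay_decay_curve(
            t, self.alpha, self.beta1, self.beta2, self.plateau, self.beta0
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alpha": self.alpha,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "plateau": self.plateau,
            "beta0": self.beta0,
        }


@dataclass(frozen=True)
class KineticMetrics:
    """Curve-derived summary metrics on a fixed evaluation horizon.

    depth_of_shrinkage : percent, 100 minus the minimum fitted volume.
    time_to_growth : days, location of the fitted minimum (decay-growth);
        flagged "no_regrowth" (horizon value) or "immediate_regrowth" (0).
    pseudo_half_life : days until the fitted curve first reaches 50% of the
        post-LITT volume; NaN when the curve never reaches 50% on the horizon
        (e.g. plateau >= 50).
    plateau : percent residual volume (decay-decay) or NaN.
    """

    depth_of_shrinkage: float
    time_to_growth: float
    ttg_flag: str
    pseudo_half_life: float
    plateau: float
    horizon: float = DEFAULT_HORIZON

    @property
    def pseudo_half_life_defined(self) -> bool:
        return np.isfinite(self.pseudo_half_life)

    def to_dict(self) -> dict:
        return {
            "depth_of_shrinkage": self.depth_of_shrinkage,
            "time_to_growth": self.time_to_growth,
            "ttg_flag": self.ttg_flag,
            "pseudo_half_life": self.pseudo_half_life,
            "plateau": self.plateau,
            "horizon": self.horizon,
        }


def derive_metrics(params: BiExpParams, horizon: float = DEFAULT_HORIZON) -> KineticMetrics:
    """Kinetic metrics of a bi-exponential curve on [0, horizon].

    Time-to-growth comes from the closed-form argmin (decay-growth); the
    pseudo-half-life from bracketed root-finding on the monotone fitted curve.
    Undefined metrics are explicit NaN states, never errors.
    """
    if params.model == "decay_growth":
        ttg, flag = time_to_growth_closed_form(
            params.alpha, params.beta1, params.beta2, horizon
        )
        v_min = float(params.predict(ttg))
        half = _first_crossing_50(params, 0.0, ttg) if v_min < 50.0 else float("nan")
        return KineticMetrics(
            depth_of_shrinkage=float(np.clip(100.0 - v_min, 0.0, 100.0)),
            time_to_growth=ttg,
            ttg_flag=flag,
            pseudo_half_life=half,
            plateau=float("nan"),
            horizon=horizon,
        )
    # decay-decay: monotone nonincreasing, minimum sits at the horizon
    v_min = float(params.predict(horizon))
    half = _first_crossing_50(params, 0.0, horizon) if v_min < 50.0 else float("nan")
    return KineticMetrics(
        depth_of_shrinkage=float(np.clip(100.0 - v_min, 0.0, 100.0)),
        time_to_growth=float("nan"),
        ttg_flag="not_applicable",
        pseudo_half_life=half,
        plateau=float(params.plateau),
        horizon=horizon,
    )


def _first_crossing_50(params: BiExpParams, lo: float, hi: float) -> float:
    f = lambda t: float(params.predict(t)) - 50.0
    if f(lo) <= 0.0:
        return lo
    if f(hi) > 0.0:
        return float("nan")
    return float(brentq(f, lo, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# percent-series construction
# ---------------------------------------------------------------------------

def to_percent_series(trajectory: LesionTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """CE series as percent of the post-LITT (day 0) volume, days >= 0 only."""
    post = trajectory.post_scan.ce_cc
    if post <= 0:
        raise NormalizationError(
            f"{trajectory.lesion_id}: post-LITT CE volume must be positive"
        )
    scans = [s for s in trajectory.analysis_scans if s.day >= 0]
    days = np.array([s.day for s in scans], dtype=float)
    percents = np.array([100.0 * s.ce_cc / post for s in scans])
    return days, percents


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class _BiExpModel:
    """Shared scaffolding for both bi-exponential model classes."""

    model_name: str = ""
    min_points: int = 3

    def __init__(self, days, percents, lesion_id: Optional[str] = None):
        days = np.asarray(days, dtype=float)
        percents = np.asarray(percents, dtype=float)
        if days.shape != percents.shape or days.ndim != 1:
            raise ValueError("days and percents must be matching 1-D arrays")
        order = np.argsort(days)
        self.days = days[order]
        self.percents = percents[order]
        self.lesion_id = lesion_id
        if self.days.size < self.min_points:
            raise InsufficientDataError(
                f"{self.model_name} needs >= {self.min_points} timepoints, "
                f"got {self.days.size}"
            )
        if self.days[0] != 0.0:
            raise InsufficientDataError("series must include the day-0 anchor")

    @classmethod
    def from_trajectory(cls, trajectory: LesionTrajectory) -> "_BiExpModel":
        days, percents = to_percent_series(trajectory)
        return cls(days, percents, lesion_id=trajectory.lesion_id)

    # subclasses define _residuals(x), _starts(), _params_from_x(x)

    def fit(self) -> "KineticsResults":
        """Bounded least squares over a deterministic multi-start grid.

        The best (lowest SSE) converged start wins; ties go to the earlier
        start in grid order.
        """
        best_x, best_sse = None, np.inf
        for x0 in self._starts():
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=self._bounds, method="trf",
                    xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=60,
                )
            except Exception:  # noqa: BLE001 - a failed start is just skipped
                continue
            sse = float(2.0 * sol.cost)
            if sse < best_sse - 1e-12:
                best_x, best_sse = sol.x, sse
        if best_x is None:
            raise FitFailureError(f"no converged start for {self.lesion_id or 'series'}")
        # polish the winning start at tight tolerance
        sol = least_squares(
            self._residuals, best_x, bounds=self._bounds, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if sol.success and 2.0 * sol.cost <= best_sse + 1e-12:
            best_x, best_sse = sol.x, float(2.0 * sol.cost)
        params = self._params_from_x(best_x)
        return KineticsResults(self, params, best_sse)


class DecayGrowthModel(_BiExpModel):
    """Progressor model: exponential decay plus exponential regrowth."""

    model_name = "decay_growth"
    min_points = 3
    _bounds = ([0.0, 0.0, 0.0], [1.0, RATE_BOUND, RATE_BOUND])

    def _residuals(self, x):
        a, b1, b2 = x
        return decay_growth_curve(self.days, a, b1, b2) - self.percents

    def _starts(self):
        for a in ALPHA_STARTS:
            for b1 in RATE_STARTS:
                for b2 in RATE_STARTS:
                    yield np.array([a, b1, b2])

    def _params_from_x(self, x) -> BiExpParams:
        a, b1, b2 = (float(v) for v in x)
        return BiExpParams("decay_growth", a, b1, b2)


class DecayDecayModel(_BiExpModel):
    """Responder model: two decays toward a residual plateau (beta1 >= beta2)."""

    model_name = "decay_decay"
    min_points = 4

    def __init__(self, days, percents, lesion_id=None):
        super().__init__(days, percents, lesion_id=lesion_id)
        # plateau cannot exceed the smallest observed percent volume
        self._plateau_max = float(max(0.0, min(self.percents.min(), BETA0 - 1e-6)))
        self._bounds = (
            [0.0, 0.0, 0.0, 0.0],
            [1.0, RATE_BOUND, 1.0, max(self._plateau_max, 1e-9)],
        )

    def _residuals(self, x):
        a, b1, s, plateau = x
        return decay_decay_curve(self.days, a, b1, b1 * s, plateau) - self.percents

    def _starts(self):
        p0 = 0.5 * self._plateau_max
        for a in ALPHA_STARTS:
            for b1 in RATE_STARTS:
                for s in RATIO_STARTS:
                    yield np.array([a, b1, s, p0])

    def _params_from_x(self, x) -> BiExpParams:
        a, b1, s, plateau = (float(v) for v in x)
        return BiExpParams("decay_decay", a, b1, b1 * s, plateau=plateau)


class KineticsResults:
    """Fit results: parameters, goodness of fit, predictions and metrics."""

    def __init__(self, model: _BiExpModel, params: BiExpParams, sse: float):
        self.model = model
        self.params = params
        self.sse = sse
        self.nobs = model.days.size

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.params.predict(self.model.days)

    @property
    def resid(self) -> np.ndarray:
        return self.model.percents - self.fittedvalues

    @property
    def rsquared(self) -> float:
        """1 - SSE/SST with SST about the mean observed percent volume."""
        sst = float(((self.model.percents - self.model.percents.mean()) ** 2).sum())
        if sst == 0.0:
            return 1.0 if self.sse < 1e-10 else float("nan")
        return 1.0 - self.sse / sst

    def predict(self, t):
        return self.params.predict(t)

    def metrics(self, horizon: float = DEFAULT_HORIZON) -> KineticMetrics:
        return derive_metrics(self.params, horizon=horizon)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Bi-exponential fit ({p.model})"
            + (f" — lesion {self.model.lesion_id}" if self.model.lesion_id else ""),
            f"  n timepoints : {self.nobs}",
            f"  alpha        : {p.alpha:.4f}",
            f"  beta1 [/day] : {p.beta1:.5f}",
            f"  beta2 [/day] : {p.beta2:.5f}",
        ]
        if p.model == "decay_decay":
            lines.append(f"  plateau [%]  : {p.plateau:.3f}")
        m = self.metrics()
        lines += [
            f"  R^2          : {self.rsquared:.2f}",
            f"  depth of shrinkage [%] : {m.depth_of_shrinkage:.1f}",
        ]
        if p.model == "decay_growth":
            lines.append(f"  time to growth [d]     : {m.time_to_growth:.1f} ({m.ttg_flag})")
        else:
            lines.append(f"  pseudo-half-life [d]   : {m.pseudo_half_life:.1f}")
        return "\n".join(lines)

    def plot(self, ax=None, horizon: Optional[float] = None):
        """Observed points and the fitted curve, percent of post-LITT volume."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hi = horizon if horizon is not None else max(self.model.days.max(), 1.0)
        tt = np.linspace(0.0, hi, 400)
        ax.plot(tt, self.predict(tt), label=f"{self.params.model} fit")
        ax.plot(self.model.days, self.model.percents, "o", label="observed")
        ax.axhline(100.0, color="grey", lw=0.5)
        ax.set_xlabel("days after LITT")
        ax.set_ylabel("CE volume [% of post-LITT]")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.model.lesion_id,
            "params": self.params.to_dict(),
            "r_squared": self.rsquared,
            "n_points": int(self.nobs),
            "metrics": self.metrics().to_dict(),
        }


# convenience function-style API matching the pipeline surface -----------------

def fit_decay_growth(days, percents, lesion_id=None) -> KineticsResults:
    """Fit the progressor (decay-growth) model; needs >= 3 points incl. day 0."""
    return DecayGrowthModel(days, percents, lesion_id=lesion_id).fit()


def fit_decay_decay(days, percents, lesion_id=None) -> KineticsResults:
    """Fit the responder (decay-decay) model; needs >= 4 points incl. day 0."""
    return DecayDecayModel(days, percents, lesion_id=lesion_id).fit()
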