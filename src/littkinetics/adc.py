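"""Group-level ADC (apparent diffusion coefficient) trend modeling.

ADC change over time, dADC(t) = ADC(t) - ADC(pre-LITT) in 1e-6 mm^2/s, is
pooled across the lesions of a response group (responders PR/LTDC vs
progressors PD < 1 y) and fitted with an ordinary-least-squares cubic
polynomial starting from the pre-LITT timepoint: each lesion contributes its
pre-LITT anchor (dADC = 0 at its true negative day) and one point per scan
with a usable ADC summary. The fit is a group-level visualization of the
dip-then-rise trend, not a lesion-level model.

The pre/post/first-follow-up paired summaries (median paired difference per
subregion with a two-sided Wilcoxon signed-rank p) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import LesionTrajectory
from .errors import InsufficientDataError
from .response import LTDC, PD_LT1Y, PR
from .stats import TestResult, wilcoxon_signed_rank

RESPONDER_GROUP = "PR/LTDC"
PROGRESSOR_GROUP = "PD<1y"

#: default mapping from response label to pooled modeling group
GROUP_OF_LABEL = {PR: RESPONDER_GROUP, LTDC: RESPONDER_GROUP,
                  PD_LT1Y: PROGRESSOR_GROUP}


def build_adc_delta_series(
    trajectories: Sequence[LesionTrajectory],
    labels: dict[str, str],
    subregion: str = "whole",
    group_of_label: dict[str, str] = GROUP_OF_LABEL,
) -> pd.DataFrame:
    """Long-format (lesion_id, group, day, delta_adc) table.

    ``labels`` maps lesion_id -> response label; lesions whose label has no
    modeling group (SD < 1 y) are skipped, as are scans with a missing ADC
    summary. The pre-LITT row carries delta_adc = 0 at its true negative day.
    Lesions with a missing pre-LITT ADC cannot anchor a delta and are skipped.
    """
    rows = []
    for traj in trajectories:
        group = group_of_label.get(labels.get(traj.lesion_id))
        if group is None:
            continue
        baseline = traj.pre_scan.adc(subregion)
        if np.isnan(baseline):
            continue
        rows.append({"lesion_id": traj.lesion_id, "group": group,
                     "day": traj.pre_scan.day, "delta_adc": 0.0})
        for s in traj.analysis_scans:
            if s.day < 0:
                continue
            val = s.adc(subregion)
            if np.isnan(val):
                continue
            rows.append({"lesion_id": traj.lesion_id, "group": group,
                         "day": s.day, "delta_adc": val - baseline})
    return pd.DataFrame(rows, columns=["lesion_id", "group", "day", "delta_adc"])


class AdcTrendModel:
    """OLS cubic polynomial on pooled (day, dADC) pairs of one group."""

    def __init__(self, days, deltas):
        days = np.asarray(days, dtype=float)
        deltas = np.asarray(deltas, dtype=float)
        if days.shape != deltas.shape or days.ndim != 1:
            raise ValueError("days and deltas must be matching 1-D arrays")
        if days.size < 5 or np.unique(days).size < 4:
            raise InsufficientDataError(
                "cubic trend needs >= 5 points on >= 4 distinct days"
            )
        self.days = days
        self.deltas = deltas

    @classmethod
    def from_series(cls, series: pd.DataFrame, group: str) -> "AdcTrendModel":
        sel = series[series["group"] == group]
        return cls(sel["day"].to_numpy(), sel["delta_adc"].to_numpy())

    def fit(self) -> "AdcTrendResults":
        # coefficients in ascending order c0..c3
        coeffs = np.polynomial.polynomial.polyfit(self.days, self.deltas, 3)
        return AdcTrendResults(self, coeffs)


class AdcTrendResults:
    """Fitted cubic: coefficients (c0..c3), predictions and residuals."""

    def __init__(self, model: AdcTrendModel, coeffs: np.ndarray):
        self.model = model
        self.coeffs = np.asarray(coeffs, dtype=float)

    def predict(self, days):
        return np.polynomial.polynomial.polyval(np.asarray(days, dtype=float),
                                                self.coeffs)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.days)

    @property
    def resid(self) -> np.ndarray:
        return self.model.deltas - self.fittedvalues

    def zero_crossings(self, lo: float = 0.0, hi: float = 1095.0) -> list[float]:
        """Days in (lo, hi) where the fitted curve crosses dADC = 0."""
        roots = np.polynomial.polynomial.polyroots(self.coeffs)
        real = roots[np.abs(roots.imag) < 1e-9].real
        return sorted(float(r) for r in real if lo < r < hi)

    def plot(self, ax=None, horizon: float = 1095.0):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tt = np.linspace(self.model.days.min(), horizon, 400)
        ax.plot(self.model.days, self.model.deltas, ".", alpha=0.4,
                label="pooled observations")
        ax.plot(tt, self.predict(tt), label="cubic trend")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("days after LITT")
        ax.set_ylabel("dADC [1e-6 mm^2/s]")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {"coefficients": list(self.coeffs),
                "n_points": int(self.model.days.size)}


def fit_adc_cubic(days, deltas) -> AdcTrendResults:
    """Function-style surface over AdcTrendModel(...).fit()."""
    return AdcTrendModel(days, deltas).fit()


# ---------------------------------------------------------------------------
# paired pre/post/FU1 summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedAdcSummary:
    subregion: str
    transition: str            # "pre_to_post" | "post_to_fu1"
    n_pairs: int
    median_difference: float   # 1e-6 mm^2/s
    test: TestResult

    @property
    def computable(self) -> bool:
        return self.n_pairs >= 2

    def to_dict(self) -> dict:
        return {
            "subregion": self.subregion,
            "transition": self.transition,
            "n_pairs": self.n_pairs,
            "median_difference": self.median_difference,
            "p_value": self.test.p_value,
        }


def _paired(trajectories, subregion, which) -> tuple[np.ndarray, np.ndarray]:
    first, second = [], []
    for traj in trajectories:
        if which == "pre_to_post":
            a, b = traj.pre_scan, traj.post_scan
        else:
            a, b = traj.post_scan, traj.fu1_scan
        if b is None:
            continue
        va, vb = a.adc(subregion), b.adc(subregion)
        if np.isnan(va) or np.isnan(vb):
            continue   # missing DWI or absent subregion: excluded pairwise
        first.append(va)
        second.append(vb)
    return np.asarray(first), np.asarray(second)


def summarize_adc_changes(
    trajectories: Sequence[LesionTrajectory],
    subregions: Sequence[str] = ("ce", "nonce", "whole"),
) -> list[PairedAdcSummary]:
    """Median paired ADC differences (pre->post, post->FU1) per subregion.

    Differences are second minus first scan, so the post-LITT ADC drop comes
    out negative. Fewer than 2 valid pairs flags the summary not-computable.
    """
    out = []
    for sub in subregions:
        for which in ("pre_to_post", "post_to_fu1"):
            a, b = _paired(trajectories, sub, which)
            diffs = b - a
            if diffs.size < 2:
                test = TestResult("wilcoxon_signed_rank", float("nan"),
                                  float("nan"), diffs.size,
                                  note="fewer than 2 valid pairs")
                med = float("nan")
            else:
                test = wilcoxon_signed_rank(b, a)
                med = float(np.median(diffs))
            out.append(PairedAdcSummary(sub, which, int(diffs.size), med, test))
    return out
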