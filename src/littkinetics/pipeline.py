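"""End-to-end cohort analysis: categorize, fit, summarize, optimize.

Thin orchestration over the per-module surfaces, shared by the CLI and by
reproduction scripts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .adc import AdcTrendModel, build_adc_delta_series, summarize_adc_changes
from .cohort import LesionTrajectory
from .errors import InsufficientDataError, NormalizationError
from .followup import TimepointPairEvaluation, evaluate_pair, find_earliest_pair
from .kinetics import DecayDecayModel, DecayGrowthModel, KineticsResults
from .response import LTDC, PD_LT1Y, PR, categorize_cohort


def fit_cohort_kinetics(
    trajectories: Sequence[LesionTrajectory],
    labels: dict[str, str],
    include_late_pd_ltdc: bool = False,
) -> dict[str, KineticsResults]:
    """Lesion-specific bi-exponential fits for the modellable categories.

    Progressors (PD < 1 y) get the decay-growth model (>= 3 timepoints),
    durable responders (PR) the decay-decay model (>= 4 timepoints). LTDC
    lesions did not necessarily shrink and are excluded by default; the
    ``include_late_pd_ltdc`` override fits them with the decay-growth model
    (the late-progression case). Lesions with too few timepoints are skipped.
    """
    fits: dict[str, KineticsResults] = {}
    for traj in trajectories:
        label = labels.get(traj.lesion_id)
        if label == PD_LT1Y:
            model_cls = DecayGrowthModel
        elif label == PR:
            model_cls = DecayDecayModel
        elif label == LTDC and include_late_pd_ltdc:
            model_cls = DecayGrowthModel
        else:
            continue
        try:
            fits[traj.lesion_id] = model_cls.from_trajectory(traj).fit()
        except (InsufficientDataError, NormalizationError):
            continue
    return fits


def summarize_kinetics(
    fits: dict[str, KineticsResults], labels: dict[str, str], horizon: float = 1095.0
) -> dict:
    """Cohort medians of the curve-derived metrics, split by category."""
    pd_fits = [f for lid, f in fits.items() if labels.get(lid) == PD_LT1Y]
    pr_fits = [f for lid, f in fits.items() if labels.get(lid) == PR]

    def med(vals):
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.median(vals)) if vals else float("nan")

    pd_metrics = [f.metrics(horizon) for f in pd_fits]
    pr_metrics = [f.metrics(horizon) for f in pr_fits]
    return {
        "n_pd_fitted": len(pd_fits),
        "n_pr_fitted": len(pr_fits),
        "median_r2_pd": med([f.rsquared for f in pd_fits]),
        "median_r2_pr": med([f.rsquared for f in pr_fits]),
        "median_time_to_growth_days": med([m.time_to_growth for m in pd_metrics]),
        "median_depth_of_shrinkage_pct": med([m.depth_of_shrinkage for m in pd_metrics]),
        "median_pseudo_half_life_days": med([m.pseudo_half_life for m in pr_metrics]),
        "median_plateau_pct": med([m.plateau for m in pr_metrics]),
    }


def optimize_followup_schedule(
    fits: dict[str, KineticsResults],
    labels: dict[str, str],
    accuracy_floor: float = 0.8,
    grid=None,
    extra_pairs: Sequence[tuple[int, int]] = ((30, 90),),
) -> dict:
    """Earliest qualifying scan pair plus evaluations of conventional pairs."""
    from .followup import DEFAULT_GRID

    lids = [lid for lid in fits if labels.get(lid) in (PD_LT1Y, PR)]
    curve_fits = [fits[lid] for lid in lids]
    is_pd = [labels[lid] == PD_LT1Y for lid in lids]
    best = find_earliest_pair(
        curve_fits, is_pd, accuracy_floor=accuracy_floor,
        grid=DEFAULT_GRID if grid is None else grid,
    )
    out = {"earliest_pair": best.to_dict() if best is not None else None}
    for t1, t2 in extra_pairs:
        out[f"pair_{t1}_{t2}"] = evaluate_pair(curve_fits, is_pd, t1, t2).to_dict()
    return out


def analyze_cohort(trajectories: Sequence[LesionTrajectory]) -> dict:
    """Full analysis of a cohort: categories, fits, metrics, schedule, ADC."""
    categories = categorize_cohort(trajectories)
    labels = {lid: c.label for lid, c in categories.items()}
    fits = fit_cohort_kinetics(trajectories, labels)
    summary = summarize_kinetics(fits, labels)
    schedule = optimize_followup_schedule(fits, labels)
    adc_summaries = summarize_adc_changes(trajectories)
    series = build_adc_delta_series(trajectories, labels, subregion="whole")
    adc_trends = {}
    for group in sorted(series["group"].unique()):
        try:
            adc_trends[group] = AdcTrendModel.from_series(series, group).fit().to_dict()
        except InsufficientDataError:
            adc_trends[group] = None
    return {
        "categories": {lid: c.to_dict() for lid, c in categories.items()},
        "fits": {lid: f.to_dict() for lid, f in fits.items()},
        "kinetic_summary": summary,
        "followup_schedule": schedule,
        "adc_paired_summaries": [s.to_dict() for s in adc_summaries],
        "adc_trends": adc_trends,
    }
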