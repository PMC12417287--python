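"""Volumetric response categorization of LITT-treated lesions.

Each lesion trajectory receives exactly one of four mutually exclusive labels
based on mRANO / RANO 2.0 volumetric thresholds applied to CE volumes:

PD_LT1Y
    progression within a year: at some scan no later than day 365 the CE
    volume reaches >= 140% of the running after-LITT nadir (the smallest
    measured CE volume from day 0 on; day 0 itself is the baseline, since
    post-LITT enlargement is expected and is not progression), and the call is
    confirmed either by a clinical decision to re-treat or by a further >= 40%
    increase measured >= 28 days after the first progression scan.
PR
    durable partial response: CE volume <= 35% of the pre-LITT volume on at
    least two consecutive scans spanning >= 28 days (only checked when the
    lesion never met PD_LT1Y).
LTDC
    long-term disease control: follow-up reaches day 365 without progression
    within the first year (progression after one year still counts as LTDC).
SD_LT1Y
    stable disease, censored before one year.

Precedence is PD_LT1Y > PR > LTDC > SD_LT1Y; "four weeks" is 28 days and
"one year" is 365 days. The rules are ratio-based, so rescaling all volumes
of a trajectory leaves the label unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import LesionTrajectory
from .errors import CategorizationError

PD_LT1Y = "PD_LT1Y"
PR = "PR"
LTDC = "LTDC"
SD_LT1Y = "SD_LT1Y"
LABELS = (PD_LT1Y, PR, LTDC, SD_LT1Y)

PD_INCREASE = 1.40        # >= 40% increase over the after-LITT nadir
PR_DECREASE = 0.35        # <= 35% of the pre-LITT volume
CONFIRM_DAYS = 28         # ">= 4 weeks"
ONE_YEAR = 365


@dataclass(frozen=True)
class ResponseCategory:
    """Label plus the evidence that triggered it."""

    label: str
    trigger: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"label": self.label, "trigger": self.trigger}


def _find_progression(trajectory: LesionTrajectory):
    """First confirmed progression event within one year, or None.

    Returns a trigger dict describing the progression scan, the reference
    (nadir) volume and how the call was confirmed.
    """
    post = trajectory.post_scan
    followups = trajectory.followup_scans
    nadir = post.ce_cc
    nadir_day = post.day
    for i, scan in enumerate(followups):
        if scan.day <= ONE_YEAR and scan.ce_cc >= PD_INCREASE * nadir:
            # candidate progression; needs retreat or a confirmatory increase
            retreated = (
                trajectory.retreated_after is not None
                and trajectory.retreated_after >= scan.day
            )
            confirm = next(
                (
                    later
                    for later in followups[i + 1:]
                    if later.day >= scan.day + CONFIRM_DAYS
                    and later.ce_cc >= PD_INCREASE * scan.ce_cc
                ),
                None,
            )
            if retreated or confirm is not None:
                return {
                    "rule": "ce >= 1.4 x after-LITT nadir, confirmed",
                    "progression_day": scan.day,
                    "reference_volume_cc": nadir,
                    "reference_day": nadir_day,
                    "confirmed_by": (
                        "retreatment"
                        if retreated
                        else f"further >=40% increase at day {confirm.day}"
                    ),
                }
        if scan.ce_cc < nadir:
            nadir = scan.ce_cc
            nadir_day = scan.day
    return None


def _find_partial_response(trajectory: LesionTrajectory):
    """Two consecutive sub-threshold scans spanning >= 28 days, or None."""
    pre = trajectory.pre_scan
    threshold = PR_DECREASE * pre.ce_cc
    scans = [trajectory.post_scan] + trajectory.followup_scans
    for a, b in zip(scans, scans[1:]):
        if (
            a.ce_cc <= threshold
            and b.ce_cc <= threshold
            and b.day - a.day >= CONFIRM_DAYS
        ):
            return {
                "rule": "ce <= 0.35 x pre-LITT volume on two scans >= 28 d apart",
                "scan_days": [a.day, b.day],
                "reference_volume_cc": pre.ce_cc,
                "reference_day": pre.day,
            }
    return None


def categorize(trajectory: LesionTrajectory) -> ResponseCategory:
    """Assign the single volumetric response label of a lesion trajectory."""
    try:
        trajectory.pre_scan
        trajectory.post_scan
    except StopIteration as exc:
        raise CategorizationError(
            f"{trajectory.lesion_id}: missing pre- or post-LITT scan"
        ) from exc

    pd_trigger = _find_progression(trajectory)
    if pd_trigger is not None:
        return ResponseCategory(PD_LT1Y, pd_trigger)

    pr_trigger = _find_partial_response(trajectory)
    if pr_trigger is not None:
        return ResponseCategory(PR, pr_trigger)

    scans = trajectory.followup_scans
    last_day = scans[-1].day if scans else trajectory.post_scan.day
    if last_day >= ONE_YEAR:
        return ResponseCategory(
            LTDC, {"rule": "stable through one year", "last_followup_day": last_day}
        )
    return ResponseCategory(
        SD_LT1Y,
        {"rule": "censored before one year without PD or PR",
         "last_followup_day": last_day},
    )


def categorize_cohort(trajectories) -> dict[str, ResponseCategory]:
    """Categorize every trajectory; returns {lesion_id: ResponseCategory}."""
    return {t.lesion_id: categorize(t) for t in trajectories}
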