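"""Per-lesion longitudinal scan series and cohort I/O.

A :class:`LesionTrajectory` holds the ordered scan series of one LITT-treated
brain metastasis: CE (contrast-enhancing), central non-CE and whole-lesion
volumes in cc, plus per-subregion ADC summaries in units of 1e-6 mm^2/s.
Days are measured relative to the LITT procedure: exactly one scan precedes
LITT (day < 0) and the immediate post-LITT scan sits at day 0.

Cohorts travel as one long-format CSV (one row per lesion-scan) with an
optional JSON ground-truth sidecar produced by the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CategorizationError

#: column order of the long-format cohort CSV
COHORT_COLUMNS = [
    "lesion_id",
    "category_truth",
    "day",
    "ce_cc",
    "nonce_cc",
    "whole_cc",
    "adc_ce",
    "adc_nonce",
    "adc_whole",
    "retreated_after",
]


@dataclass(frozen=True)
class Scan:
    """One MRI timepoint of a lesion.

    ADC summaries may be NaN when the subregion is absent on that scan or the
    diffusion acquisition is missing.
    """

    day: int
    ce_cc: float
    nonce_cc: float
    whole_cc: float
    adc_ce: float = float("nan")
    adc_nonce: float = float("nan")
    adc_whole: float = float("nan")

    def adc(self, subregion: str) -> float:
        return getattr(self, f"adc_{subregion}")


@dataclass
class LesionTrajectory:
    """Ordered scan series of one lesion, anchored on the LITT day.

    Parameters
    ----------
    lesion_id : str
    scans : sequence of Scan
        Strictly increasing days; exactly one scan with day < 0 (pre-LITT)
        and one with day == 0 (immediate post-LITT); volumes >= 0.
    retreated_after : int, optional
        Day on which a clinical decision to re-treat was made. Not computable
        from imaging, so it is an input flag.
    censoring_day : int, optional
        Scans after this day are ignored by the analysis.
    """

    lesion_id: str
    scans: Sequence[Scan]
    retreated_after: Optional[int] = None
    censoring_day: Optional[int] = None
    category_truth: Optional[str] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda s: s.day)
        days = [s.day for s in self.scans]
        if len(set(days)) != len(days):
            raise ValueError(f"{self.lesion_id}: duplicate scan days {days}")
        if sum(1 for d in days if d < 0) != 1:
            raise ValueError(f"{self.lesion_id}: need exactly one pre-LITT scan (day < 0)")
        if sum(1 for d in days if d == 0) != 1:
            raise ValueError(f"{self.lesion_id}: need exactly one post-LITT scan (day 0)")
        for s in self.scans:
            if min(s.ce_cc, s.nonce_cc, s.whole_cc) < 0:
                raise ValueError(f"{self.lesion_id}: negative volume at day {s.day}")

    # -- anchored reference scans -------------------------------------------------
    @property
    def pre_scan(self) -> Scan:
        return next(s for s in self.scans if s.day < 0)

    @property
    def post_scan(self) -> Scan:
        return next(s for s in self.scans if s.day == 0)

    @property
    def followup_scans(self) -> list[Scan]:
        """Scans strictly after the post-LITT scan, up to censoring."""
        out = [s for s in self.scans if s.day > 0]
        if self.censoring_day is not None:
            out = [s for s in out if s.day <= self.censoring_day]
        return out

    @property
    def analysis_scans(self) -> list[Scan]:
        """All scans up to censoring (pre-LITT included)."""
        if self.censoring_day is None:
            return list(self.scans)
        return [s for s in self.scans if s.day <= self.censoring_day]

    @property
    def fu1_scan(self) -> Optional[Scan]:
        """First follow-up scan after the immediate post-LITT scan."""
        fus = self.followup_scans
        return fus[0] if fus else None

    def days(self) -> np.ndarray:
        return np.array([s.day for s in self.analysis_scans])

    def ce_volumes(self) -> np.ndarray:
        return np.array([s.ce_cc for s in self.analysis_scans])


def require_anchors(trajectory: LesionTrajectory) -> None:
    """Raise CategorizationError when the pre/post-LITT anchors are missing."""
    try:
        trajectory.pre_scan
        trajectory.post_scan
    except StopIteration as exc:  # pragma: no cover - guarded in __post_init__
        raise CategorizationError(
            f"{trajectory.lesion_id}: missing pre- or post-LITT scan"
        ) from exc


# ---------------------------------------------------------------------------
# cohort <-> long-format CSV
# ---------------------------------------------------------------------------

def cohort_to_frame(trajectories: Sequence[LesionTrajectory]) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        for s in traj.scans:
            rows.append(
                {
                    "lesion_id": traj.lesion_id,
                    "category_truth": traj.category_truth,
                    "day": s.day,
                    "ce_cc": s.ce_cc,
                    "nonce_cc": s.nonce_cc,
                    "whole_cc": s.whole_cc,
                    "adc_ce": s.adc_ce,
                    "adc_nonce": s.adc_nonce,
                    "adc_whole": s.adc_whole,
                    "retreated_after": traj.retreated_after,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[LesionTrajectory]:
    trajectories = []
    for lesion_id, grp in frame.groupby("lesion_id", sort=False):
        scans = [
            Scan(
                day=int(r.day),
                ce_cc=float(r.ce_cc),
                nonce_cc=float(r.nonce_cc),
                whole_cc=float(r.whole_cc),
                adc_ce=float(r.adc_ce),
                adc_nonce=float(r.adc_nonce),
                adc_whole=float(r.adc_whole),
            )
            for r in grp.itertuples()
        ]
        retreat = grp["retreated_after"].iloc[0]
        category = grp["category_truth"].iloc[0] if "category_truth" in grp else None
        trajectories.append(
            LesionTrajectory(
                lesion_id=str(lesion_id),
                scans=scans,
                retreated_after=None if pd.isna(retreat) else int(retreat),
                category_truth=None if pd.isna(category) else str(category),
            )
        )
    return trajectories


def write_cohort_csv(trajectories: Sequence[LesionTrajectory], path) -> None:
    cohort_to_frame(trajectories).to_csv(path, index=False)


def read_cohort_csv(path) -> list[LesionTrajectory]:
    return frame_to_cohort(pd.read_csv(path))


def write_ground_truth_json(records, path) -> None:
    """Serialize GroundTruthRecord dataclasses (simulate module) to JSON."""
    payload = [r.to_dict() for r in records]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
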