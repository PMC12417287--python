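"""Synthetic LITT cohort and digital lesion phantom generation.

The cohort generator emulates the statistical structure the downstream
analysis assumes: per category,

* progressors (PD < 1 y) follow the decay-growth bi-exponential with a
  confirmed >= 40% regrowth over the after-LITT nadir inside the first year;
* durable responders (PR) follow the decay-decay bi-exponential toward a
  small residual plateau, crossing the -65%-of-pre-LITT threshold on at
  least two scans >= 4 weeks apart;
* long-term disease control (LTDC) lesions decay mildly toward a high
  plateau and are followed past one year;
* stable lesions (SD < 1 y) barely change and are censored early.

Noise-free CE percent volume at day 0 is exactly 100 for every lesion.
Observed volumes are the noise-free values times multiplicative lognormal
noise whose coefficient of variation equals ``volume_noise_cv`` (volumes are
positive and measurement error scales with size); ADC noise is additive
Gaussian. Scan days get uniform integer jitter around a nominal schedule;
follow-up truncation is deterministic per category, reproducing the cohort's
follow-up-duration contrast (responders followed ~3 years, progressors a few
months). The pre-LITT scan sits at a sampled day in [-30, -1]; LITT is day 0,
and the post-LITT CE volume is the pre-LITT volume times a sampled
enlargement factor (the expected heat-induced blood-brain-barrier surge).

ADC trajectories follow a dip-then-rise template (monotone piecewise-cubic
through anchor points): drop at day 0, an optional further dip at ~40-55
days, and for responders a rise crossing baseline at ~6-9 months.

Phantoms for the segmentation front end are analytic spherical-shell lesions
(enhancing rim around a hypointense core) with known rim/core volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy.interpolate import PchipInterpolator

from .cohort import LesionTrajectory, Scan
from .errors import ConfigurationError, DegeneratePhantomError
from .kinetics import (
    BiExpParams,
    KineticMetrics,
    RATE_BOUND,
    derive_metrics,
)
from .response import LTDC, PD_LT1Y, PR, SD_LT1Y

#: nominal follow-up schedule (days after LITT); pre-LITT and day-0 scans are
#: implicit. Mirrors a ~3-year follow-up with early scans at ~1/2/3 months.
DEFAULT_SCHEDULE = (33, 63, 95, 130, 180, 270, 365, 550, 730, 1000)

SUBREGIONS = ("ce", "nonce", "whole")


def _check_range(name: str, lo: float, hi: float, bounds=None) -> None:
    if not lo <= hi:
        raise ConfigurationError(f"{name}: empty range ({lo}, {hi})")
    if bounds is not None and not (bounds[0] <= lo and hi <= bounds[1]):
        raise ConfigurationError(
            f"{name}: range ({lo}, {hi}) outside {bounds}"
        )


@dataclass(frozen=True)
class ParameterPriors:
    """Uniform sampling ranges for the ground-truth curve coefficients.

    Rate coefficients are constrained to the model's admissible [0, 0.1]/day
    band. Responder plateaus stay below the durable-PR threshold implied by
    the smallest admissible enlargement factor, so every noise-free PR
    trajectory can fire the -65% rule; control-category plateaus stay above
    it so they cannot.
    """

    pd_alpha: tuple = (0.60, 0.95)
    pd_beta1: tuple = (0.02, 0.10)
    pd_beta2: tuple = (0.015, 0.05)

    pr_alpha: tuple = (0.15, 0.45)
    pr_beta1: tuple = (0.02, 0.08)
    pr_beta2: tuple = (0.004, 0.009)
    pr_plateau: tuple = (0.0, 8.0)

    ltdc_alpha: tuple = (0.20, 0.60)
    ltdc_beta1: tuple = (0.02, 0.08)
    ltdc_beta2: tuple = (0.004, 0.01)
    ltdc_plateau: tuple = (45.0, 85.0)

    sd_alpha: tuple = (0.20, 0.60)
    sd_beta1: tuple = (0.02, 0.08)
    sd_beta2: tuple = (0.004, 0.01)
    sd_plateau: tuple = (70.0, 95.0)

    pre_ce_cc: tuple = (0.7, 4.7)           # pre-LITT CE volume [cc]
    enlargement: tuple = (1.3, 2.3)         # post-LITT / pre-LITT CE ratio

    def validate(self) -> None:
        for name in ("pd_beta1", "pd_beta2", "pr_beta1", "pr_beta2",
                     "ltdc_beta1", "ltdc_beta2", "sd_beta1", "sd_beta2"):
            _check_range(name, *getattr(self, name), bounds=(0.0, RATE_BOUND))
        for name in ("pd_alpha", "pr_alpha", "ltdc_alpha", "sd_alpha"):
            _check_range(name, *getattr(self, name), bounds=(0.0, 1.0))
        for name in ("pr_plateau", "ltdc_plateau", "sd_plateau"):
            _check_range(name, *getattr(self, name), bounds=(0.0, 100.0))
        _check_range("pre_ce_cc", *self.pre_ce_cc, bounds=(1e-6, np.inf))
        _check_range("enlargement", *self.enlargement, bounds=(1.0, np.inf))
        # the PR rule threshold is 0.35 * 100 / enlargement percent of post-LITT
        pr_threshold_floor = 35.0 / self.enlargement[1]
        if self.pr_plateau[1] >= pr_threshold_floor:
            raise ConfigurationError(
                "pr_plateau upper bound must stay below the durable-PR "
                f"threshold floor ({pr_threshold_floor:.1f}%)"
            )


@dataclass(frozen=True)
class DropoutRule:
    """Deterministic per-category follow-up truncation.

    SD lesions are censored after ``sd_last_day``; PD lesions keep
    ``pd_extra_scans`` scans beyond the first progression scan (at which the
    clinical re-treat decision is recorded); responders/LTDC keep the full
    schedule, optionally capped.
    """

    sd_last_day: int = 70
    pd_extra_scans: int = 1
    pr_last_day: Optional[int] = None
    ltdc_last_day: Optional[int] = None


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort recipe; the defaults emulate the study cohort shape
    (17 PR / 12 PD < 1 y / 4 LTDC / 14 SD < 1 y lesions)."""

    n_pr: int = 17
    n_pd: int = 12
    n_ltdc: int = 4
    n_sd: int = 14
    scan_schedule: Sequence[int] = DEFAULT_SCHEDULE
    day_jitter: int = 3                      # uniform integer jitter [days]
    volume_noise_cv: float = 0.05            # CV of multiplicative volume noise
    adc_noise_sd: float = 30.0               # additive ADC noise [1e-6 mm^2/s]
    parameter_priors: ParameterPriors = field(default_factory=ParameterPriors)
    dropout: DropoutRule = field(default_factory=DropoutRule)
    missing_dwi_prob: float = 0.04           # scans lacking a DWI acquisition
    absent_nonce_prob: float = 0.08          # lesions with no pre-LITT core
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pr", "n_pd", "n_ltdc", "n_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.volume_noise_cv < 0:
            raise ConfigurationError("volume_noise_cv must be >= 0")
        if self.adc_noise_sd < 0:
            raise ConfigurationError("adc_noise_sd must be >= 0")
        if self.day_jitter < 0:
            raise ConfigurationError("day_jitter must be >= 0")
        sched = list(self.scan_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])) or (sched and sched[0] <= 0):
            raise ConfigurationError("scan_schedule must be strictly increasing, > 0")
        self.parameter_priors.validate()


@dataclass(frozen=True)
class GroundTruthRecord:
    """What the generator actually used for one lesion, for recovery testing."""

    lesion_id: str
    true_category: str
    true_params: BiExpParams
    true_metrics: KineticMetrics
    pre_ce_cc: float
    post_ce_cc: float
    enlargement: float

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "true_category": self.true_category,
            "true_params": self.true_params.to_dict(),
            "true_metrics": self.true_metrics.to_dict(),
            "pre_ce_cc": self.pre_ce_cc,
            "post_ce_cc": self.post_ce_cc,
            "enlargement": self.enlargement,
        }


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sample_params(category: str, priors: ParameterPriors, rng) -> BiExpParams:
    if category == PD_LT1Y:
        return BiExpParams(
            "decay_growth",
            alpha=rng.uniform(*priors.pd_alpha),
            beta1=rng.uniform(*priors.pd_beta1),
            beta2=rng.uniform(*priors.pd_beta2),
        )
    prefix = {PR: "pr", LTDC: "ltdc", SD_LT1Y: "sd"}[category]
    b1 = rng.uniform(*getattr(priors, f"{prefix}_beta1"))
    b2 = rng.uniform(*getattr(priors, f"{prefix}_beta2"))
    b1, b2 = max(b1, b2), min(b1, b2)     # decay-decay convention beta1 >= beta2
    return BiExpParams(
        "decay_decay",
        alpha=rng.uniform(*getattr(priors, f"{prefix}_alpha")),
        beta1=b1,
        beta2=b2,
        plateau=rng.uniform(*getattr(priors, f"{prefix}_plateau")),
    )


def _jittered_schedule(config: CohortConfig, rng) -> list[int]:
    days = []
    prev = 0
    for nominal in config.scan_schedule:
        j = int(rng.integers(-config.day_jitter, config.day_jitter + 1)) \
            if config.day_jitter else 0
        day = max(nominal + j, prev + 1)  # keep strictly increasing, > day 0
        days.append(day)
        prev = day
    return days


def _truncate_for_category(
    category: str, days: list[int], params: BiExpParams, dropout: DropoutRule
) -> tuple[list[int], Optional[int]]:
    """Apply the per-category follow-up truncation; returns (days, retreat day)."""
    if category == SD_LT1Y:
        return [d for d in days if d <= dropout.sd_last_day], None
    if category == PR and dropout.pr_last_day is not None:
        return [d for d in days if d <= dropout.pr_last_day], None
    if category == LTDC and dropout.ltdc_last_day is not None:
        return [d for d in days if d <= dropout.ltdc_last_day], None
    if category == PD_LT1Y:
        # follow until the noise-free curve first exceeds 140% of its running
        # nadir (the progression scan, where the re-treat decision falls),
        # plus a fixed number of confirmatory scans
        pct = params.predict(np.array(days, dtype=float))
        nadir = 100.0
        for i, (d, v) in enumerate(zip(days, pct)):
            if d <= 365 and v >= 1.4 * nadir:
                last = min(len(days), i + 1 + dropout.pd_extra_scans)
                return days[:last], d
            nadir = min(nadir, v)
        # priors guarantee progression inside the schedule; guard anyway
        return days, days[-1]
    return days, None


def _nonce_template(pre_day: int, n0: float, category: str) -> PchipInterpolator:
    """Central non-CE (necrotic core) volume template in cc."""
    peak = n0 + 1.6
    if category in (PR, LTDC):
        anchors_x = [pre_day, 0, 45, 365, 1095]
        anchors_y = [n0, n0 + 0.3, peak, 0.6 * peak, 0.3 * peak]
    else:
        anchors_x = [pre_day, 0, 45, 365, 1095]
        anchors_y = [n0, n0 + 0.3, peak, peak, peak]
    return PchipInterpolator(anchors_x, anchors_y)


#: per-subregion ADC baselines and day-0 drops [1e-6 mm^2/s]; drops follow the
#: observed medians (CE -101, central non-CE -224, whole -137)
_ADC_BASELINE = {"ce": (1000.0, 1250.0), "nonce": (1350.0, 1650.0),
                 "whole": (1100.0, 1350.0)}
_ADC_DROP0 = {"ce": -101.0, "nonce": -224.0, "whole": -137.0}
_ADC_DIP = {"ce": -60.0, "nonce": -10.0, "whole": -52.0}


def _adc_template(pre_day: int, category: str, subregion: str, rng) -> PchipInterpolator:
    base = rng.uniform(*_ADC_BASELINE[subregion])
    drop0 = _ADC_DROP0[subregion] * rng.uniform(0.6, 1.4)
    dip_day = rng.uniform(35.0, 55.0)
    dip = _ADC_DIP[subregion] * rng.uniform(0.5, 1.5)
    if category in (PR, LTDC):
        # rises above baseline at ~6-9 months and plateaus at an elevated
        # long-term level once necrotic debris has cleared
        cross_day = rng.uniform(180.0, 270.0)
        elevation = 250.0 * rng.uniform(0.7, 1.3)
        xs = [pre_day, 0.0, dip_day, cross_day, cross_day + 150.0, 1095.0]
        ys = [base, base + drop0, base + drop0 + dip, base,
              base + elevation, base + elevation]
    else:
        xs = [pre_day, 0.0, dip_day, 365.0, 1095.0]
        ys = [base, base + drop0, base + drop0 + dip, base - 30.0, base + 20.0]
    return PchipInterpolator(xs, ys)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[LesionTrajectory], list[GroundTruthRecord]]:
    """Generate a synthetic cohort plus its ground truth.

    Same config and seed produce a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.volume_noise_cv**2)))

    plan = (
        [PR] * config.n_pr + [PD_LT1Y] * config.n_pd
        + [LTDC] * config.n_ltdc + [SD_LT1Y] * config.n_sd
    )
    trajectories: list[LesionTrajectory] = []
    truths: list[GroundTruthRecord] = []
    for idx, category in enumerate(plan):
        lesion_id = f"L{idx + 1:03d}"
        pre_day = int(rng.integers(-30, 0))
        pre_ce = rng.uniform(*config.parameter_priors.pre_ce_cc)
        enlargement = rng.uniform(*config.parameter_priors.enlargement)
        post_ce = pre_ce * enlargement
        params = _sample_params(category, config.parameter_priors, rng)

        followup_days = _jittered_schedule(config, rng)
        followup_days, retreat_day = _truncate_for_category(
            category, followup_days, params, config.dropout
        )

        days = [pre_day, 0] + followup_days
        # noise-free CE volumes [cc]: pre-LITT from the enlargement factor,
        # day >= 0 from the category's bi-exponential curve
        post_days = np.array([0] + followup_days, dtype=float)
        true_pct = params.predict(post_days)
        true_ce = np.concatenate([[pre_ce], post_ce * true_pct / 100.0])

        nonce_absent_pre = rng.random() < config.absent_nonce_prob
        n0 = 0.0 if nonce_absent_pre else rng.uniform(0.2, 1.0)
        nonce_f = _nonce_template(pre_day, n0, category)
        true_nonce = np.clip(nonce_f(np.array(days, dtype=float)), 0.0, None)

        adc_f = {r: _adc_template(pre_day, category, r, rng) for r in SUBREGIONS}

        scans = []
        for i, day in enumerate(days):
            ce = true_ce[i] * float(np.exp(rng.normal(0.0, sigma)))
            nonce = true_nonce[i] * float(np.exp(rng.normal(0.0, sigma)))
            whole = ce + nonce
            missing_dwi = rng.random() < config.missing_dwi_prob
            adc = {}
            for r in SUBREGIONS:
                val = float(adc_f[r](day)) + float(rng.normal(0.0, config.adc_noise_sd))
                if missing_dwi or (r == "nonce" and day < 0 and nonce_absent_pre):
                    val = float("nan")
                adc[r] = val
            scans.append(
                Scan(
                    day=int(day), ce_cc=ce, nonce_cc=nonce, whole_cc=whole,
                    adc_ce=adc["ce"], adc_nonce=adc["nonce"], adc_whole=adc["whole"],
                )
            )
        trajectories.append(
            LesionTrajectory(
                lesion_id=lesion_id,
                scans=scans,
                retreated_after=retreat_day,
                category_truth=category,
            )
        )
        truths.append(
            GroundTruthRecord(
                lesion_id=lesion_id,
                true_category=category,
                true_params=params,
                true_metrics=derive_metrics(params),
                pre_ce_cc=pre_ce,
                post_ce_cc=post_ce,
                enlargement=enlargement,
            )
        )
    return trajectories, truths


def noise_free_trajectory(
    truth: GroundTruthRecord, trajectory: LesionTrajectory
) -> LesionTrajectory:
    """Rebuild a trajectory with its noise-free CE volumes (same scan days)."""
    scans = []
    for s in trajectory.scans:
        if s.day < 0:
            ce = truth.pre_ce_cc
        else:
            ce = truth.post_ce_cc * float(truth.true_params.predict(s.day)) / 100.0
        scans.append(
            Scan(day=s.day, ce_cc=ce, nonce_cc=s.nonce_cc, whole_cc=ce + s.nonce_cc,
                 adc_ce=s.adc_ce, adc_nonce=s.adc_nonce, adc_whole=s.adc_whole)
        )
    return LesionTrajectory(
        lesion_id=trajectory.lesion_id,
        scans=scans,
        retreated_after=trajectory.retreated_after,
        category_truth=trajectory.category_truth,
    )


# ---------------------------------------------------------------------------
# analytic lesion phantom
# ---------------------------------------------------------------------------

@dataclass
class LesionPhantom:
    """Spherical-shell phantom: enhancing rim around a hypointense core."""

    t1_img: nib.Nifti1Image
    adc_img: nib.Nifti1Image
    contour_img: nib.Nifti1Image
    rim_mask: np.ndarray
    core_mask: np.ndarray
    truth: dict


def simulate_lesion_phantom(
    outer_radius_mm: float = 10.0,
    inner_radius_mm: float = 6.0,
    rim_intensity: float = 0.9,
    core_intensity: float = 0.2,
    background_intensity: float = 0.05,
    rim_adc: float = 700.0,
    core_adc: float = 400.0,
    background_adc: float = 900.0,
    voxel_size: tuple = (1.0, 1.0, 1.0),
    margin_mm: float = 6.0,
    contour_margin_mm: float = 2.0,
    t1_noise_sd: float = 0.01,
    adc_noise_sd: float = 5.0,
    seed: int = 0,
) -> LesionPhantom:
    """Build a 3-D spherical-shell lesion phantom with known subregion volumes.

    The enhancing rim occupies inner_radius < d <= outer_radius and the
    hypointense core d <= inner_radius, on a darker background. Images carry a
    diagonal affine from ``voxel_size``; the contour mask is the lesion sphere
    padded by ``contour_margin_mm``. Same seed gives identical voxel data.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if min(voxel_size) <= 0:
        raise DegeneratePhantomError("voxel dimensions must be positive")
    if outer_radius_mm < max(voxel_size):
        raise DegeneratePhantomError("outer radius smaller than one voxel")
    if not (0 <= inner_radius_mm < outer_radius_mm):
        raise DegeneratePhantomError("need 0 <= inner radius < outer radius")
    if not rim_intensity > 0.7 > core_intensity > background_intensity >= 0:
        raise DegeneratePhantomError(
            "need rim > 0.7 > core > background intensity ordering"
        )

    rng = np.random.default_rng(seed)
    extent = outer_radius_mm + contour_margin_mm + margin_mm
    shape = tuple(int(np.ceil(2 * extent / v)) | 1 for v in voxel_size)  # odd dims
    center = np.array([(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size)])
    coords = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(shape, voxel_size)], indexing="ij"
    )
    dist = np.sqrt(sum((c - mu) ** 2 for c, mu in zip(coords, center)))

    core = dist <= inner_radius_mm
    rim = (dist <= outer_radius_mm) & ~core
    contour = dist <= outer_radius_mm + contour_margin_mm

    t1 = np.full(shape, background_intensity, dtype=float)
    t1[rim] = rim_intensity
    t1[core] = core_intensity
    t1 += rng.normal(0.0, t1_noise_sd, shape)

    adc = np.full(shape, background_adc, dtype=float)
    adc[rim] = rim_adc
    adc[core] = core_adc
    adc += rng.normal(0.0, adc_noise_sd, shape)

    affine = np.diag(list(voxel_size) + [1.0])
    voxel_volume = float(np.prod(voxel_size))
    truth = {
        "rim_volume_mm3_analytic": 4.0 / 3.0 * np.pi
        * (outer_radius_mm**3 - inner_radius_mm**3),
        "core_volume_mm3_analytic": 4.0 / 3.0 * np.pi * inner_radius_mm**3,
        "rim_volume_mm3_voxel": float(rim.sum()) * voxel_volume,
        "core_volume_mm3_voxel": float(core.sum()) * voxel_volume,
        "rim_adc": rim_adc,
        "core_adc": core_adc,
        "voxel_volume_mm3": voxel_volume,
    }
    return LesionPhantom(
        t1_img=nib.Nifti1Image(t1, affine),
        adc_img=nib.Nifti1Image(adc, affine),
        contour_img=nib.Nifti1Image(contour.astype(np.uint8), affine),
        rim_mask=rim,
        core_mask=core,
        truth=truth,
    )
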