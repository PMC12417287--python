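import numpy as np
import pytest
from hypothesis import settings

import littkinetics as lk

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 10 PR + 10 PD cohort with ground truth (shared, read-only)."""
    config = lk.CohortConfig(n_pr=10, n_pd=10, n_ltdc=0, n_sd=0,
                             volume_noise_cv=0.05, seed=42)
    return lk.simulate_cohort(config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Default-shape cohort with zero volume noise (shared, read-only)."""
    config = lk.CohortConfig(volume_noise_cv=0.0, seed=42)
    return lk.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    trajectories, truths = small_cohort
    labels = {t.lesion_id: t.category_truth for t in trajectories}
    fits = lk.fit_cohort_kinetics(trajectories, labels)
    return fits, labels, {t.lesion_id: t for t in truths}


@pytest.fixture(scope="session")
def shell_phantom():
    """Default 10/6 mm spherical-shell phantom at 1 mm isotropic voxels."""
    return lk.simulate_lesion_phantom(seed=7)


def make_trajectory(ce_by_day, lesion_id="T1", retreated_after=None, **volumes):
    """Trajectory with the given {day: ce_cc}; non-CE fixed small."""
    scans = [
        lk.Scan(day=day, ce_cc=ce, nonce_cc=0.2, whole_cc=ce + 0.2)
        for day, ce in sorted(ce_by_day.items())
    ]
    return lk.LesionTrajectory(lesion_id=lesion_id, scans=scans,
                               retreated_after=retreated_after)
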