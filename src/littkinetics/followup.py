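"""Model-driven follow-up schedule optimization.

Using the fitted lesion-specific volume curves, search for the earliest pair
of theoretical follow-up days (t1, t2) that separates progressors (PD < 1 y)
from durable responders (PR) with accuracy >= 0.8 and a significant Fisher
exact test. The classifier applied at a pair is the volumetric progression
threshold evaluated on the fitted curve: the t1 value (capped at 100%) serves
as the nadir proxy, and a lesion is flagged PD when the t2 value reaches 140%
of that proxy, or when the t1 value itself already reached 140% of the
post-LITT volume.

"Earliest" orders candidate pairs by the later scan day t2 first (the scan
that gates the clinical decision), then by t1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EvaluationError
from .stats import fisher_exact

PD_FLAG_RATIO = 1.4
DEFAULT_GRID = range(7, 366)


@dataclass(frozen=True)
class TimepointPairEvaluation:
    """Diagnostic performance of one (t1, t2) candidate schedule.

    "Positive" means progression. Identities: tp + fn = number of PD lesions,
    tn + fp = number of PR lesions, accuracy = (tp + tn) / total.
    """

    t1: float
    t2: float
    tp: int
    fp: int
    tn: int
    fn: int
    fisher_p: float

    def __post_init__(self):
        if not 0 < self.t1 < self.t2:
            raise ValueError("need 0 < t1 < t2")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "t1": self.t1, "t2": self.t2,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fisher_p": self.fisher_p,
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy/sensitivity/specificity identities from an integer matrix."""
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def classify_at_pair(fit, t1: float, t2: float) -> bool:
    """PD flag of one fitted curve at a theoretical scan pair.

    ``fit`` is anything with a ``predict(day)`` method (a KineticsResults or
    BiExpParams). Nadir proxy = min(100, predict(t1)); flag PD iff
    predict(t2) >= 1.4 * nadir proxy, or predict(t1) >= 140.
    """
    if not t1 < t2:
        raise ValueError("need t1 < t2")
    v1 = float(fit.predict(t1))
    v2 = float(fit.predict(t2))
    nadir_proxy = min(100.0, v1)
    return bool(v2 >= PD_FLAG_RATIO * nadir_proxy or v1 >= 140.0)


def evaluate_pair(
    fits: Sequence, is_pd: Sequence[bool], t1: float, t2: float
) -> TimepointPairEvaluation:
    """Confusion matrix and Fisher exact p of a candidate pair over a cohort."""
    is_pd = np.asarray(is_pd, dtype=bool)
    if len(fits) != is_pd.size:
        raise ValueError("fits and is_pd must align")
    if is_pd.all() or not is_pd.any():
        raise EvaluationError("need at least one lesion in each category")
    flags = np.array([classify_at_pair(f, t1, t2) for f in fits])
    tp = int(np.sum(flags & is_pd))
    fp = int(np.sum(flags & ~is_pd))
    fn = int(np.sum(~flags & is_pd))
    tn = int(np.sum(~flags & ~is_pd))
    p = fisher_exact([[tp, fn], [fp, tn]]).p_value
    return TimepointPairEvaluation(t1=t1, t2=t2, tp=tp, fp=fp, tn=tn, fn=fn,
                                   fisher_p=float(p))


def find_earliest_pair(
    fits: Sequence,
    is_pd: Sequence[bool],
    accuracy_floor: float = 0.8,
    grid: Sequence[int] = DEFAULT_GRID,
    alpha: Optional[float] = 0.05,
) -> Optional[TimepointPairEvaluation]:
    """Earliest qualifying (t1, t2) over the day grid, or None.

    Qualifying means accuracy >= ``accuracy_floor`` and Fisher p < ``alpha``
    (pass ``alpha=None`` to drop the significance gate);
    candidates are scanned in (t2, t1) lexicographic order, so the returned
    pair minimizes t2 with ties broken by minimal t1. Predictions are
    precomputed per grid day; the scan itself matches an exhaustive
    brute-force search over the same grid.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 2:
        raise EvaluationError("grid must contain at least two days")
    is_pd = np.asarray(is_pd, dtype=bool)
    if is_pd.all() or not is_pd.any():
        raise EvaluationError("need at least one lesion in each category")

    pred = np.vstack([np.asarray(f.predict(grid), dtype=float) for f in fits])
    n_pd = int(is_pd.sum())
    n_pr = int((~is_pd).sum())
    total = n_pd + n_pr

    for j in range(1, grid.size):
        v2 = pred[:, j]
        for i in range(j):
            v1 = pred[:, i]
            flags = (v2 >= PD_FLAG_RATIO * np.minimum(100.0, v1)) | (v1 >= 140.0)
            tp = int(np.sum(flags & is_pd))
            tn = int(np.sum(~flags & ~is_pd))
            if (tp + tn) / total < accuracy_floor:
                continue
            p = fisher_exact([[tp, n_pd - tp], [n_pr - tn, tn]]).p_value
            if alpha is None or p < alpha:
                return TimepointPairEvaluation(
                    t1=float(grid[i]), t2=float(grid[j]),
                    tp=tp, fp=n_pr - tn, tn=tn, fn=n_pd - tp,
                    fisher_p=float(p),
                )
    return None
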