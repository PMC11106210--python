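"""Cross-validated detector evaluation under a false-positive budget.

Annotated segments are shuffled into k folds.  For each hyperparameter
combination and each fold, a detector is trained on the complement (the
template-based TFSB method needs no training), run on the fold's
segments, and scored by

* false-positive rate — the fraction of detected chirp times that fall
  inside no ground-truth chirp interval, and
* false-negative rate — the fraction of ground-truth chirps that contain
  no detected time,

with detections and ground-truth counts pooled over the fold's segments
and rates averaged over folds.  Hyperparameters are then tuned by
minimizing the mean false-negative rate subject to a cap on the mean
false-positive rate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .gt_processing import ResampledSample
from .signal_extraction import OscillationSeries

logger = logging.getLogger(__name__)


class BudgetInfeasibleError(ValueError):
    """No hyperparameter combination meets the false-positive budget."""


@dataclass
class SegmentData:
    """One evaluation unit: a series slice plus its ground-truth chirps."""

    segment_id: int
    series: OscillationSeries
    samples: list[ResampledSample]

    def gt_intervals(self) -> list[tuple[float, float]]:
        return [(s.t_first, s.t_last) for s in self.samples]


@dataclass
class CVResult:
    params: dict
    fp_per_fold: list[float]
    fn_per_fold: list[float]
    feasible: bool = True

    @property
    def mean_fp(self) -> float:
        return float(np.mean(self.fp_per_fold)) if self.fp_per_fold else float("nan")

    @property
    def mean_fn(self) -> float:
        return float(np.mean(self.fn_per_fold)) if self.fn_per_fold else float("nan")


# ---------------------------------------------------------------------------
# folds and rates
# ---------------------------------------------------------------------------

def split_folds(ids: Sequence, k: int, seed: int) -> list[list]:
    """Seeded shuffle then round-robin split into k folds (sizes differ <= 1)."""
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} ids into {k} folds")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return folds


def fp_fn_rates(
    detections: dict[int, Sequence[float]],
    gt: dict[int, Sequence[tuple[float, float]]],
) -> tuple[float, float]:
    """Pooled false-positive and false-negative rates over a set of segments.

    ``detections`` maps segment id -> detected chirp times; ``gt`` maps
    segment id -> closed ground-truth intervals [t_first, t_last].  With
    zero detections the FP rate is defined as 0 (nothing was falsely
    called); with zero ground-truth chirps the FN rate is defined as 0.
    """
    n_det = 0
    n_fp = 0
    n_gt = 0
    n_hit = 0
    for seg in gt:
        times = np.asarray(detections.get(seg, ()), dtype=float)
        intervals = gt[seg]
        n_det += times.size
        n_gt += len(intervals)
        if times.size:
            inside_any = np.zeros(times.size, dtype=bool)
            for lo, hi in intervals:
                inside_any |= (times >= lo) & (times <= hi)
            n_fp += int((~inside_any).sum())
        for lo, hi in intervals:
            if times.size and np.any((times >= lo) & (times <= hi)):
                n_hit += 1
    fp = n_fp / n_det if n_det else 0.0
    fn = 1.0 - n_hit / n_gt if n_gt else 0.0
    return fp, fn


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

#: a detector factory receives one hyperparameter dict and the training
#: samples and returns a callable mapping a series to detected chirp times;
#: it raises to mark the combination infeasible for that fold.
DetectorFactory = Callable[
    [dict, list[ResampledSample]], Callable[[OscillationSeries], Sequence[float]]
]


def expand_grid(axes: dict[str, Iterable]) -> list[dict]:
    """Cartesian product of hyperparameter axes, in axis-major order."""
    keys = list(axes)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(list(axes[k]) for k in keys))
    ]


def cross_validate(
    detector_factory: DetectorFactory,
    grid: list[dict],
    segments: list[SegmentData],
    k: int,
    seed: int,
) -> list[CVResult]:
    """k-fold cross-validation of a detector over a hyperparameter grid.

    Fold units are whole segments.  For every combination h and fold q the
    detector is built from the complement folds' ground-truth samples and
    evaluated on fold q's segments.  A training failure marks h infeasible
    (logged, excluded from optimization) rather than aborting the search.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    seg_ids = [s.segment_id for s in segments]
    by_id = {s.segment_id: s for s in segments}
    folds = split_folds(seg_ids, k, seed)

    results: list[CVResult] = []
    for h in grid:
        fps, fns = [], []
        feasible = True
        for q, test_ids in enumerate(folds):
            train_samples = [
                smp
                for sid in seg_ids
                if sid not in test_ids
                for smp in by_id[sid].samples
            ]
            try:
                detect = detector_factory(h, train_samples)
            except Exception as exc:  # noqa: BLE001 - any training failure
                logger.warning("h=%s infeasible on fold %d: %s", h, q, exc)
                feasible = False
                break
            detections = {
                sid: list(detect(by_id[sid].series)) for sid in test_ids
            }
            gt = {sid: by_id[sid].gt_intervals() for sid in test_ids}
            fp, fn = fp_fn_rates(detections, gt)
            fps.append(fp)
            fns.append(fn)
        results.append(CVResult(dict(h), fps, fns, feasible=feasible))
    return results


# ---------------------------------------------------------------------------
# FP-budgeted optimization
# ---------------------------------------------------------------------------

def optimize_hyperparameters(
    results: list[CVResult], r_fp: float
) -> tuple[dict, float]:
    """Minimize mean FN over combinations whose mean FP is within budget.

    Ties break toward the lower mean FP, then toward grid order.
    """
    if not results:
        raise ValueError("no cross-validation results")
    feasible = [r for r in results if r.feasible and r.mean_fp <= r_fp]
    if not feasible:
        best_fp = min(
            (r.mean_fp for r in results if r.feasible), default=float("nan")
        )
        raise BudgetInfeasibleError(
            f"no combination achieves mean FP <= {r_fp} "
            f"(smallest achieved: {best_fp})"
        )
    best = min(feasible, key=lambda r: (r.mean_fn, r.mean_fp))
    return best.params, best.mean_fn


def fn_curve(
    results: list[CVResult], budgets: Sequence[float]
) -> list[tuple[float, float | None]]:
    """Lowest achievable mean FN per FP budget (None where infeasible).

    Non-increasing in the budget: a larger feasible set can only help.
    """
    if list(budgets) != sorted(budgets):
        raise ValueError("budgets must be sorted ascending")
    curve: list[tuple[float, float | None]] = []
    for b in budgets:
        try:
            _, r_fn = optimize_hyperparameters(results, b)
        except BudgetInfeasibleError:
            r_fn = None
        curve.append((float(b), r_fn))
    return curve
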