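"""Precision-recall curves with non-linear interpolation and moving baseline.

The PR curve plots precision TP/(TP+FP) against recall TP/P over all
thresholds. Unlike ROC, its random baseline is not fixed: a random
classifier attains precision P/(P+N) at every recall, so the baseline — and
the AUC of a random classifier — moves with the class ratio.

Interpolation between two PR points A and B is NOT a straight line.
Walking from A to B adds true positives one at a time while false
positives accrue at the segment's local skew (FP_B - FP_A)/(TP_B - TP_A);
after x additional true positives (0 <= x <= TP_B - TP_A) the precision is

    y = (TP_A + x) / (TP_A + x + FP_A + (FP_B - FP_A) * x / (TP_B - TP_A))

which traces a hyperbolic arc. Linear interpolation in PR space
systematically overstates the area; this module densifies each segment at
unit-TP resolution (or finer) before applying trapezoids.

Every ROC point corresponds one-to-one to a PR point once P and N are
fixed; :func:`roc_to_pr` and :func:`pr_to_roc` convert both ways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scores import ThresholdSweep


@dataclass(frozen=True)
class PrSegment:
    """A PR-space segment between supports A and B with integer counts.

    ``x`` in ``[0, TP_B - TP_A]`` parameterises the segment as the number
    of additional true positives beyond A; at x = 0 the interpolant
    reproduces A exactly and at x = TP_B - TP_A it reproduces B.
    """

    tp_a: int
    fp_a: int
    tp_b: int
    fp_b: int
    n_pos: int

    def __post_init__(self) -> None:
        if min(self.tp_a, self.fp_a, self.tp_b, self.fp_b) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp_b <= self.tp_a:
            raise ValueError(
                "segment requires TP_B > TP_A; a constant-TP segment is vertical "
                "in PR space and is connected without interpolation"
            )
        if self.n_pos < self.tp_b:
            raise ValueError("n_pos must be at least TP_B")

    @property
    def skew(self) -> float:
        """False positives accrued per additional true positive."""
        return (self.fp_b - self.fp_a) / (self.tp_b - self.tp_a)


def interpolate_pr(seg: PrSegment, x: float) -> tuple[float, float]:
    """Evaluate the non-linear PR interpolant at x added true positives.

    Returns ``(recall, precision)`` with recall = (TP_A + x)/P and
    precision from the count-based hyperbolic formula.
    """
    span = seg.tp_b - seg.tp_a
    if not (0 <= x <= span):
        raise ValueError(f"x must lie in [0, {span}], got {x}")
    tp = seg.tp_a + x
    fp = seg.fp_a + seg.skew * x
    recall = tp / seg.n_pos
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    return recall, precision


@dataclass(frozen=True)
class PrCurve:
    """Realized PR points with integer supports, plus a recall-0 anchor.

    ``recall``/``precision`` hold the points actually visited by the
    threshold sweep (zero-prediction element excluded), each backed by its
    integer ``(tp, fp)`` support so that precision == tp/(tp+fp) exactly.
    ``anchor_precision`` is the limit value used to anchor the curve at
    recall 0; it equals the x -> 0 limit of the interpolant on the first
    segment out of the origin support (tp = fp = 0), i.e. the precision of
    the first positive-yielding point, or 0 when the top of the ranking is
    pure false positives.
    """

    recall: np.ndarray
    precision: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    anchor_precision: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        recall = np.asarray(self.recall, dtype=float)
        precision = np.asarray(self.precision, dtype=float)
        tp = np.asarray(self.tp, dtype=np.int64)
        fp = np.asarray(self.fp, dtype=np.int64)
        if not (recall.shape == precision.shape == tp.shape == fp.shape):
            raise ValueError("point arrays must share one shape")
        if np.any(np.diff(recall) < 0):
            raise ValueError("recall must be non-decreasing")
        object.__setattr__(self, "recall", recall)
        object.__setattr__(self, "precision", precision)
        object.__setattr__(self, "tp", tp)
        object.__setattr__(self, "fp", fp)

    @property
    def baseline(self) -> float:
        """Precision of a random classifier: P / (P + N)."""
        return prc_baseline(self.n_pos, self.n_neg)

    def __len__(self) -> int:
        return len(self.recall)


def prc_baseline(n_pos: int, n_neg: int) -> float:
    """The moving PRC baseline y = P / (P + N).

    0.5 for balanced data; 1/11 (about 0.09) at a 1:10 ratio. Undefined
    without positives.
    """
    if n_pos < 1:
        raise ValueError("baseline undefined for P = 0")
    if n_neg < 0:
        raise ValueError("N must be non-negative")
    return n_pos / (n_pos + n_neg)


def prc_points(sweep: ThresholdSweep) -> PrCurve:
    """Map a threshold sweep to PR space.

    Every sweep element with at least one positive prediction becomes the
    point (TP/P, TP/(TP+FP)). The all-negative element has no defined
    precision and is excluded; instead the curve records the recall-0
    anchor precision (see :class:`PrCurve`).
    """
    mask = (sweep.tp + sweep.fp) >= 1
    tp = sweep.tp[mask]
    fp = sweep.fp[mask]
    # collapse consecutive duplicates (mirrors roc_points)
    keep = np.r_[True, (np.diff(tp) != 0) | (np.diff(fp) != 0)]
    tp, fp = tp[keep], fp[keep]
    recall = tp / sweep.n_pos
    precision = tp / (tp + fp)
    if tp[0] > 0:
        anchor = float(tp[0] / (tp[0] + fp[0]))
    else:
        anchor = 0.0
    return PrCurve(
        recall=recall,
        precision=precision,
        tp=tp,
        fp=fp,
        n_pos=sweep.n_pos,
        n_neg=sweep.n_neg,
        anchor_precision=anchor,
        provenance=dict(sweep.provenance),
    )


def densify_pr(curve: PrCurve, steps_per_tp: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Expand the curve into interpolated (recall, precision) arrays.

    Each segment with increasing TP is evaluated at ``steps_per_tp``
    sub-steps per unit true positive via the non-linear interpolant;
    constant-TP segments appear as precision drops at constant recall. The
    output starts at (0, anchor_precision) and ends at recall 1.
    """
    if steps_per_tp < 1:
        raise ValueError("steps_per_tp must be >= 1")
    rec_parts = [np.array([0.0])]
    prec_parts = [np.array([curve.anchor_precision])]
    # prepend the origin support so the first segment is interpolated too
    tp = np.r_[0, curve.tp]
    fp = np.r_[0, curve.fp]
    # drop the prepended origin if the first realized point is itself at tp=0
    if len(curve.tp) and curve.tp[0] == 0 and curve.fp[0] == 0:
        tp, fp = tp[1:], fp[1:]
    for a in range(len(tp) - 1):
        dtp = int(tp[a + 1] - tp[a])
        if dtp == 0:
            # vertical drop: same recall, lower precision
            rec_parts.append(np.array([tp[a + 1] / curve.n_pos]))
            prec_parts.append(np.array([tp[a + 1] / (tp[a + 1] + fp[a + 1])]))
            continue
        seg = PrSegment(
            tp_a=int(tp[a]), fp_a=int(fp[a]), tp_b=int(tp[a + 1]), fp_b=int(fp[a + 1]),
            n_pos=curve.n_pos,
        )
        xs = np.arange(1, dtp * steps_per_tp + 1) / steps_per_tp
        tpx = seg.tp_a + xs
        fpx = seg.fp_a + seg.skew * xs
        rec_parts.append(tpx / curve.n_pos)
        prec_parts.append(tpx / (tpx + fpx))
    return np.concatenate(rec_parts), np.concatenate(prec_parts)


def auc_prc(curve: PrCurve, steps_per_tp: int = 1) -> float:
    """Area under the non-linearly interpolated PR curve over recall [0, 1].

    Segments are densified at unit-TP resolution (or finer) and the area
    is accumulated by trapezoids on the densified points. With the default
    ``steps_per_tp=1`` this agrees with averaging interpolated precision
    over the P unit-recall steps to within the trapezoid end corrections.
    """
    rec, prec = densify_pr(curve, steps_per_tp=steps_per_tp)
    return float(np.trapezoid(prec, rec))


def roc_to_pr(
    point: tuple[float, float],
    n_pos: int,
    n_neg: int,
    atol: float = 1e-6,
) -> tuple[float, float]:
    """Convert one ROC point (fpr, tpr) to PR space for fixed P, N.

    The implied counts tp = tpr*P and fp = fpr*N must be integral to
    within ``atol``; the correspondence is exact and invertible whenever
    precision > 0.
    """
    fpr, tpr = point
    tp = tpr * n_pos
    fp = fpr * n_neg
    for name, v in (("tp", tp), ("fp", fp)):
        if abs(v - round(v)) > atol * max(1.0, abs(v)):
            raise ValueError(f"{name} = {v} is not integral within tolerance")
    tp, fp = round(tp), round(fp)
    if tp + fp == 0:
        raise ValueError("the all-negative point has no PR image (no positive predictions)")
    return tp / n_pos, tp / (tp + fp)


def pr_to_roc(
    point: tuple[float, float],
    n_pos: int,
    n_neg: int,
    atol: float = 1e-6,
) -> tuple[float, float]:
    """Convert one PR point (recall, precision) back to ROC space."""
    recall, precision = point
    if precision <= 0:
        raise ValueError("precision must be positive to recover the ROC point")
    tp = recall * n_pos
    fp = tp * (1 - precision) / precision
    for name, v in (("tp", tp), ("fp", fp)):
        if abs(v - round(v)) > atol * max(1.0, abs(v)):
            raise ValueError(f"{name} = {v} is not integral within tolerance")
    return round(fp) / n_neg, round(tp) / n_pos
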