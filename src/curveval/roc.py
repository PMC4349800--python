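"""ROC curves, trapezoidal AUC and the ROC convex hull.

The ROC curve plots the true-positive rate TPR = TP/P against the
false-positive rate FPR = FP/N over all thresholds. A random classifier
traces the diagonal from (0, 0) to (1, 1) with AUC 0.5; a perfect one
passes through (0, 1) with AUC 1. Both axes are class-conditional rates,
so the curve (and its AUC) is unchanged by the P:N ratio.

The convex hull — the upper convex envelope of the ROC points — estimates
the best performance achievable by interpolating (randomising) between the
classifier's thresholds; its AUC is never below the raw curve's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .scores import ThresholdSweep


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC points with class totals and provenance.

    Starts at (0, 0), ends at (1, 1); fpr and tpr are non-decreasing.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or len(fpr) < 2:
            raise ValueError("fpr and tpr must be equal-length 1-D arrays of >= 2 points")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("ROC curve must start at (0,0) and end at (1,1)")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    def __len__(self) -> int:
        return len(self.fpr)


def roc_points(sweep: ThresholdSweep) -> RocCurve:
    """Map a threshold sweep to ROC space: (FP/N, TP/P) per matrix.

    Consecutive duplicate points (possible when tied instances of one class
    repeat a corner) are collapsed, keeping the first occurrence; this is
    cosmetic and does not change the area.
    """
    fpr = sweep.fp / sweep.n_neg
    tpr = sweep.tp / sweep.n_pos
    keep = np.r_[True, (np.diff(fpr) != 0) | (np.diff(tpr) != 0)]
    return RocCurve(
        fpr=fpr[keep],
        tpr=tpr[keep],
        n_pos=sweep.n_pos,
        n_neg=sweep.n_neg,
        provenance=dict(sweep.provenance),
    )


def auc_trapezoid(curve: Union[RocCurve, tuple[np.ndarray, np.ndarray]]) -> float:
    """Trapezoidal area under a curve whose x is non-decreasing.

    Accepts a :class:`RocCurve` or a plain ``(x, y)`` pair (e.g. a
    magnifier-transformed curve).
    """
    if isinstance(curve, RocCurve):
        x, y = curve.fpr, curve.tpr
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be non-decreasing for trapezoidal integration")
    return float(np.trapezoid(y, x))


def convex_hull(curve: RocCurve) -> RocCurve:
    """Upper convex envelope of the ROC points.

    Monotone-chain upper hull over the point set; collinear interior
    points are dropped. The hull's vertices are a subset of the input
    points and always include (0, 0) and (1, 1).
    """
    pts = np.column_stack([curve.fpr, curve.tpr])
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            # a on or below the chord o->p is not an upper-hull vertex; the
            # tolerance absorbs float fuzz on exactly collinear rate triples
            if cross >= -1e-12:
                hull.pop()
            else:
                break
        # skip exact duplicates
        if hull and hull[-1][0] == p[0] and hull[-1][1] == p[1]:
            continue
        hull.append(p)
    arr = np.array(hull)
    return RocCurve(
        fpr=arr[:, 0],
        tpr=arr[:, 1],
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
        provenance={**curve.provenance, "convex_hull": True},
    )
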