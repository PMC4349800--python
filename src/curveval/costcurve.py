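"""Cost curves: normalized expected cost against the probability-cost function.

A cost curve summarises a classifier across operating conditions — class
priors p(+), p(-) and misclassification costs C(-|+) (a positive called
negative) and C(+|-) (a negative called positive). The operating point on
the x-axis is the probability-cost function for positives,

    PCF(+) = p(+) C(-|+) / (p(+) C(-|+) + p(-) C(+|-)),

and the y-axis is the normalized expected cost of one threshold,

    NE[C] = FNR * PCF(+) + FPR * (1 - PCF(+)),

a straight line from (0, FPR) to (1, FNR); with equal costs and priors it
reduces to the error rate. Each ROC point is one such line (point-line
duality); the classifier's cost curve is the lower envelope of all its
lines, including the trivial always-negative (NE[C] = PCF) and
always-positive (NE[C] = 1 - PCF) classifiers, so the envelope never
exceeds min(PCF, 1 - PCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scores import ThresholdSweep


@dataclass(frozen=True)
class CostSetup:
    """Class priors and misclassification costs defining operating points.

    ``c_fn`` is C(-|+), the cost of misclassifying a positive as negative;
    ``c_fp`` is C(+|-), the cost of misclassifying a negative as positive.
    """

    p_pos: float
    p_neg: float
    c_fn: float
    c_fp: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_pos <= 1 and 0 <= self.p_neg <= 1):
            raise ValueError("class probabilities must lie in [0, 1]")
        if abs(self.p_pos + self.p_neg - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.c_fn <= 0 or self.c_fp <= 0:
            raise ValueError("misclassification costs must be positive")


def pcf_plus(setup: CostSetup) -> float:
    """Probability-cost function for positives at one operating condition.

    PCF(+) = p(+)C(-|+) / (p(+)C(-|+) + p(-)C(+|-)). With equal costs it
    reduces to the positive prior p(+); cost asymmetry shifts the
    operating point (e.g. priors 0.09/0.91 with costs 91/9 land back at
    0.5).
    """
    num = setup.p_pos * setup.c_fn
    denom = num + setup.p_neg * setup.c_fp
    if denom == 0:
        raise ValueError("PCF(+) undefined: zero total probability-cost")
    return num / denom


def nec_line(fpr, fnr, pcf):
    """Normalized expected cost of one threshold at operating point(s) pcf.

    The straight line NE[C] = fnr*pcf + fpr*(1 - pcf), running from
    (0, fpr) to (1, fnr) in cost space. Vectorised over any argument.
    """
    fpr = np.asarray(fpr, dtype=float)
    fnr = np.asarray(fnr, dtype=float)
    pcf = np.asarray(pcf, dtype=float)
    if np.any((fpr < 0) | (fpr > 1)) or np.any((fnr < 0) | (fnr > 1)):
        raise ValueError("fpr and fnr must lie in [0, 1]")
    if np.any((pcf < 0) | (pcf > 1)):
        raise ValueError("pcf must lie in [0, 1]")
    out = fnr * pcf + fpr * (1.0 - pcf)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CostCurve:
    """Lower envelope of per-threshold cost lines on a PCF grid."""

    pcf: np.ndarray
    nec: np.ndarray
    fpr: np.ndarray  # one entry per contributing threshold line
    fnr: np.ndarray
    provenance: dict = field(default_factory=dict)


def cost_envelope(sweep: ThresholdSweep, grid_size: int = 1000) -> CostCurve:
    """Lower envelope of the sweep's cost lines over a uniform PCF grid.

    Each sweep element contributes the line (FPR, FNR); the sweep already
    contains the two trivial classifiers (all-negative: line pcf;
    all-positive: line 1 - pcf) as its first and last elements, so the
    envelope is bounded above by min(pcf, 1 - pcf) everywhere. The grid
    holds ``grid_size`` evenly spaced points spanning [0, 1].
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    fpr = sweep.fp / sweep.n_neg
    fnr = sweep.fn / sweep.n_pos
    # deduplicate identical lines
    lines = np.unique(np.column_stack([fpr, fnr]), axis=0)
    grid = np.linspace(0.0, 1.0, grid_size)
    # nec[i, j] = cost of line i at grid point j
    nec = lines[:, 1:2] * grid[None, :] + lines[:, 0:1] * (1.0 - grid[None, :])
    envelope = nec.min(axis=0)
    return CostCurve(
        pcf=grid,
        nec=envelope,
        fpr=lines[:, 0],
        fnr=lines[:, 1],
        provenance=dict(sweep.provenance),
    )
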