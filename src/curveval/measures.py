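"""Single-threshold evaluation measures derived from a confusion matrix.

A binary classifier evaluated at one score threshold produces four outcome
counts — true positives (TP), false negatives (FN), false positives (FP)
and true negatives (TN) — from which all basic measures follow: accuracy,
error rate, sensitivity (= TPR = recall), specificity, false positive rate,
precision (= PPV), the Matthews correlation coefficient and the F-beta
family. Precision, MCC and F-beta are the only measures in this set that
react to class imbalance; the others are invariant under changes of the
P:N ratio that preserve the per-class rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


@dataclass(frozen=True)
class ConfusionMatrix:
    """The four outcomes of binary classification at one threshold.

    Attributes
    ----------
    tp, fn, fp, tn
        Non-negative counts. ``tp + fn`` is the number of actual positives
        (P) and ``fp + tn`` the number of actual negatives (N).
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def pos(self) -> int:
        """Number of actual positives P = TP + FN."""
        return self.tp + self.fn

    @property
    def neg(self) -> int:
        """Number of actual negatives N = FP + TN."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.pos + self.neg


@dataclass(frozen=True)
class MeasureSet:
    """Basic measures computed from one confusion matrix.

    ``prec`` is ``None`` when no instance was predicted positive
    (TP + FP = 0): the ratio is undefined and is reported as missing rather
    than silently coerced to 0 or 1. F-beta scores that depend on an
    undefined precision are ``None`` as well.
    """

    acc: float
    err: float
    sn: float
    sp: float
    fpr: float
    prec: Optional[float]
    mcc: float
    fbeta: Mapping[float, Optional[float]] = field(default_factory=dict)

    # aliases used interchangeably in the field
    @property
    def tpr(self) -> float:
        return self.sn

    @property
    def rec(self) -> float:
        return self.sn

    @property
    def ppv(self) -> Optional[float]:
        return self.prec

    def as_dict(self) -> dict:
        """Flat key -> value record, suitable for JSON/TSV serialization."""
        out = {
            "acc": self.acc,
            "err": self.err,
            "sn": self.sn,
            "sp": self.sp,
            "fpr": self.fpr,
            "prec": self.prec,
            "mcc": self.mcc,
        }
        for beta, val in self.fbeta.items():
            out[f"f{beta:g}"] = val
        return out


def fbeta(prec: float, rec: float, beta: float) -> float:
    """F-beta score: the weighted harmonic mean of precision and recall.

        F_beta = (1 + beta^2) * prec * rec / (beta^2 * prec + rec)

    ``beta`` weights recall relative to precision; common choices are
    0.5, 1 and 2. By convention ``prec = rec = 0`` yields 0.

    Parameters
    ----------
    prec, rec
        Values in [0, 1].
    beta
        Positive weight.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if not (0 <= prec <= 1 and 0 <= rec <= 1):
        raise ValueError("prec and rec must lie in [0, 1]")
    b2 = beta * beta
    denom = b2 * prec + rec
    if denom == 0:
        return 0.0
    return (1 + b2) * prec * rec / denom


def compute_measures(
    cm: ConfusionMatrix,
    betas: Sequence[float] = (0.5, 1.0, 2.0),
    allow_single_class: bool = False,
) -> MeasureSet:
    """Evaluate every basic measure on a confusion matrix.

    Degenerate ratios follow an explicit policy: precision with
    TP + FP = 0 is reported as ``None`` (missing), and MCC with any zero
    factor in its denominator is 0, the conventional limit. All values are
    computed in floating point from the integer cells with no internal
    rounding.

    Parameters
    ----------
    cm
        A valid confusion matrix with at least one instance.
    betas
        F-beta weights to evaluate.
    allow_single_class
        When False (default), a matrix whose positive or negative class is
        empty raises, since class-conditional rates are undefined; pass
        True to receive the partial measures with NaN in the undefined
        slots.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix: no data to evaluate")
    if not allow_single_class and (cm.pos == 0 or cm.neg == 0):
        raise ValueError(
            "both classes must be present (tp+fn >= 1 and fp+tn >= 1); "
            "pass allow_single_class=True for partial measures"
        )

    tp, fn, fp, tn = float(cm.tp), float(cm.fn), float(cm.fp), float(cm.tn)
    total = tp + fn + fp + tn

    acc = (tp + tn) / total
    err = (fp + fn) / total
    sn = tp / (tp + fn) if cm.pos else math.nan
    sp = tn / (tn + fp) if cm.neg else math.nan
    fpr = fp / (tn + fp) if cm.neg else math.nan

    prec: Optional[float]
    prec = tp / (tp + fp) if (tp + fp) > 0 else None

    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_denom) if mcc_denom > 0 else 0.0

    fb: dict[float, Optional[float]] = {}
    for beta in betas:
        if prec is None:
            fb[beta] = None
        elif math.isnan(sn):
            fb[beta] = None
        else:
            fb[beta] = fbeta(prec, sn, beta)

    return MeasureSet(acc=acc, err=err, sn=sn, sp=sp, fpr=fpr, prec=prec, mcc=mcc, fbeta=fb)
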