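"""Scored, labelled instances and threshold sweeps.

A classifier that outputs a real-valued score per instance is evaluated
model-wide by sweeping a decision threshold from above the highest score
(everything predicted negative) down past the lowest score (everything
predicted positive). Higher scores mean "more likely positive"; the
prediction rule is ``score >= threshold`` -> predicted positive.

Tied scores need an explicit policy, because a block of instances sharing
one score offers no internal ordering. Three standard choices:

* ``upper``  — count the block's positives before any of its negatives
  (the optimistic staircase),
* ``lower``  — count the negatives first (pessimistic),
* ``average`` — emit only the block's end point, so curves cross the block
  along the straight chord; this is the default and matches the
  pair-counting (Mann-Whitney) treatment of ties as one half.

Missing scores (e.g. instances removed by a pre-filter) are handled by
assigning one shared default value strictly below every observed score,
which turns them into a terminal tie block: under the average policy the
ROC curve continues linearly to (1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Optional, Sequence

import numpy as np

from .measures import ConfusionMatrix

TiePolicy = Literal["upper", "lower", "average"]

_TIE_POLICIES = ("upper", "lower", "average")


class MissingScoreError(ValueError):
    """Raised when an operation requires fully scored data."""


@dataclass(frozen=True)
class ScoredDataset:
    """Instance scores (possibly missing) with binary labels.

    Attributes
    ----------
    scores
        Float array; entries flagged in ``missing`` carry no information
        (their numeric slot is NaN, never a sentinel value).
    labels
        Boolean array, True for positives.
    missing
        Boolean mask of unscored instances.
    """

    scores: np.ndarray
    labels: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        missing = np.asarray(self.missing, dtype=bool)
        if not (len(scores) == len(labels) == len(missing)):
            raise ValueError("scores, labels and missing must have equal length")
        if len(scores) == 0:
            raise ValueError("dataset must contain at least one instance")
        if np.isnan(scores[~missing]).any():
            raise ValueError("non-missing scores must be finite numbers")
        scores = scores.copy()
        scores[missing] = np.nan
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "missing", missing)

    @classmethod
    def from_items(
        cls,
        scores: Iterable[Optional[float]],
        labels: Iterable[bool | int],
    ) -> "ScoredDataset":
        """Build from Python sequences; ``None`` marks a missing score."""
        raw = list(scores)
        missing = np.array([s is None for s in raw], dtype=bool)
        vals = np.array([np.nan if s is None else float(s) for s in raw], dtype=float)
        return cls(vals, np.asarray(list(labels), dtype=bool), missing)

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())


@dataclass(frozen=True)
class ThresholdSweep:
    """Confusion matrices along a descending-score threshold sweep.

    The sequence starts at the all-negative prediction (tp = fp = 0) and
    ends at the all-positive prediction (fn = tn = 0); tp and fp are
    non-decreasing. Stored as parallel count arrays for efficiency;
    iteration yields :class:`ConfusionMatrix` objects.
    """

    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    tie_policy: TiePolicy = "average"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tp = np.asarray(self.tp, dtype=np.int64)
        fp = np.asarray(self.fp, dtype=np.int64)
        if tp.shape != fp.shape or tp.ndim != 1:
            raise ValueError("tp and fp must be 1-D arrays of equal length")
        if np.any(np.diff(tp) < 0) or np.any(np.diff(fp) < 0):
            raise ValueError("tp and fp must be non-decreasing along the sweep")
        if tp[0] != 0 or fp[0] != 0:
            raise ValueError("sweep must start at the all-negative prediction")
        if tp[-1] != self.n_pos or fp[-1] != self.n_neg:
            raise ValueError("sweep must end at the all-positive prediction")
        object.__setattr__(self, "tp", tp)
        object.__setattr__(self, "fp", fp)

    @property
    def fn(self) -> np.ndarray:
        return self.n_pos - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n_neg - self.fp

    def __len__(self) -> int:
        return len(self.tp)

    def __iter__(self) -> Iterator[ConfusionMatrix]:
        for tp, fp in zip(self.tp, self.fp):
            yield ConfusionMatrix(
                tp=int(tp), fn=self.n_pos - int(tp), fp=int(fp), tn=self.n_neg - int(fp)
            )


def rank_scores(ds: ScoredDataset) -> np.ndarray:
    """Rank scores from lowest (rank 1) to highest (rank n).

    Tied scores keep their order of occurrence in the input, i.e. the
    earlier instance receives the lower rank (stable ranking).

    Raises
    ------
    MissingScoreError
        If any score is missing; impute first with
        :func:`apply_missing_default`.
    """
    if ds.has_missing:
        raise MissingScoreError(
            "dataset has missing scores; apply_missing_default() before ranking"
        )
    order = np.argsort(ds.scores, kind="stable")
    ranks = np.empty(ds.n, dtype=np.int64)
    ranks[order] = np.arange(1, ds.n + 1)
    return ranks


def apply_missing_default(
    ds: ScoredDataset, default_policy: str = "min_minus_one"
) -> ScoredDataset:
    """Replace missing scores with one shared value below every observed score.

    All unscored instances receive the same default, forming a single tie
    block at the bottom of the ranking; with the average tie policy the ROC
    curve then runs straight from the last scored point to (1, 1). The
    default is ``min(observed) - 1``; any value strictly below the minimum
    is equivalent, this one is fixed for reproducibility.
    """
    if default_policy != "min_minus_one":
        raise ValueError(f"unknown missing-default policy: {default_policy!r}")
    if not ds.has_missing:
        return ds
    observed = ds.scores[~ds.missing]
    if observed.size == 0:
        raise ValueError("all scores are missing; no observed minimum to anchor on")
    filled = ds.scores.copy()
    filled[ds.missing] = observed.min() - 1.0
    return ScoredDataset(filled, ds.labels, np.zeros(ds.n, dtype=bool))


def sweep_confusions(ds: ScoredDataset, tie_policy: TiePolicy = "average") -> ThresholdSweep:
    """Sweep thresholds over distinct scores, descending, into confusion matrices.

    One threshold per distinct score value (rule: ``score >= threshold`` is
    predicted positive), preceded by the all-negative matrix. Within a
    block of tied scores containing both classes, the tie policy decides
    the path: ``upper`` emits the corner after the block's positives,
    ``lower`` after its negatives, ``average`` emits only the block's end
    point so downstream curves take the straight chord.
    """
    if tie_policy not in _TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {_TIE_POLICIES}, got {tie_policy!r}")
    if ds.has_missing:
        raise MissingScoreError(
            "dataset has missing scores; apply_missing_default() before sweeping"
        )
    n_pos, n_neg = ds.n_pos, ds.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curve construction needs at least one positive and one negative")

    order = np.argsort(-ds.scores, kind="stable")
    sorted_scores = ds.scores[order]
    sorted_pos = ds.labels[order].astype(np.int64)

    # block boundaries over runs of equal score
    block_start = np.flatnonzero(np.r_[True, sorted_scores[1:] != sorted_scores[:-1]])
    pos_in_block = np.add.reduceat(sorted_pos, block_start)
    tot_in_block = np.diff(np.r_[block_start, len(sorted_scores)])
    neg_in_block = tot_in_block - pos_in_block

    tp_list = [0]
    fp_list = [0]
    cum_tp = 0
    cum_fp = 0
    for bp, bn in zip(pos_in_block, neg_in_block):
        if bp > 0 and bn > 0 and tie_policy != "average":
            if tie_policy == "upper":
                tp_list.append(cum_tp + int(bp))
                fp_list.append(cum_fp)
            else:  # lower
                tp_list.append(cum_tp)
                fp_list.append(cum_fp + int(bn))
        cum_tp += int(bp)
        cum_fp += int(bn)
        tp_list.append(cum_tp)
        fp_list.append(cum_fp)

    return ThresholdSweep(
        tp=np.array(tp_list),
        fp=np.array(fp_list),
        n_pos=n_pos,
        n_neg=n_neg,
        tie_policy=tie_policy,
        provenance={"tie_policy": tie_policy},
    )


def confusion_at_threshold(ds: ScoredDataset, threshold: float) -> ConfusionMatrix:
    """Confusion matrix at one fixed threshold (``score >= threshold`` -> positive)."""
    if ds.has_missing:
        raise MissingScoreError("impute missing scores before thresholding")
    pred_pos = ds.scores >= threshold
    tp = int(np.sum(pred_pos & ds.labels))
    fp = int(np.sum(pred_pos & ~ds.labels))
    fn = int(np.sum(~pred_pos & ds.labels))
    tn = int(np.sum(~pred_pos & ~ds.labels))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
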