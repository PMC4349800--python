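"""Reading score tables, writing curve exports, and worked-example fixtures.

Input format: a TSV or CSV with a header and two mandatory columns,
``score`` (decimal number with a dot separator; an empty cell marks a
missing score) and ``label`` (a configurable token for positives, default
``1``). Curve exports are TSV files with two columns (x, y) printed at
full double precision plus a JSON sidecar holding the AUC and the
policies used, so every figure has an exactly reproducible text twin.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .measures import ConfusionMatrix
from .scores import ScoredDataset

PathLike = Union[str, Path]

#: threshold at which the worked-example confusion-matrix fixtures are read
FIXTURE_THRESHOLD = 0.5

FIXTURE_KINDS = ("worked_example", "table2_balanced", "table2_imbalanced")


def read_scores(
    path: PathLike,
    positive_label: str = "1",
    negative_label: Optional[str] = None,
    sep: Optional[str] = None,
) -> ScoredDataset:
    """Read a score/label table into a :class:`ScoredDataset`.

    Parameters
    ----------
    path
        TSV (default for ``.tsv``) or CSV file with ``score`` and
        ``label`` columns.
    positive_label
        Token marking positives.
    negative_label
        Token marking negatives; when None, every non-positive token is
        accepted as negative provided only one such token occurs.
    sep
        Field separator; inferred from the extension when None.

    Raises
    ------
    ValueError
        On unparseable score cells (with the offending line number) or
        unknown label tokens.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("score", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    n = len(df)
    if n == 0:
        raise ValueError(f"{path}: no data rows")
    scores = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    for i, raw in enumerate(df["score"].tolist()):
        cell = raw.strip()
        if cell == "":
            missing[i] = True
            continue
        try:
            scores[i] = float(cell)
        except ValueError:
            # +2: one for the header, one for 1-based numbering
            raise ValueError(f"{path}: unparseable score {raw!r} at line {i + 2}") from None

    tokens = df["label"].str.strip()
    is_pos = tokens == positive_label
    others = sorted(set(tokens[~is_pos]))
    if negative_label is not None:
        bad = [t for t in others if t != negative_label]
    else:
        bad = others[1:]  # more than one distinct non-positive token is ambiguous
    if bad:
        first = int(np.flatnonzero(tokens.isin(bad))[0])
        raise ValueError(
            f"{path}: unknown label token {tokens.iloc[first]!r} at line {first + 2}"
        )
    return ScoredDataset(scores, is_pos.to_numpy(), missing)


def write_scores(path: PathLike, ds: ScoredDataset, sep: str = "\t") -> None:
    """Write a dataset back to a score/label table (empty cell = missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"score{sep}label\n")
        for s, lab, miss in zip(ds.scores, ds.labels, ds.missing):
            cell = "" if miss else format(float(s), ".17g")
            fh.write(f"{cell}{sep}{1 if lab else 0}\n")


def write_curve(
    path_tsv: PathLike,
    x: np.ndarray,
    y: np.ndarray,
    sidecar: Optional[Mapping] = None,
    x_name: str = "x",
    y_name: str = "y",
) -> None:
    """Write a curve as TSV (full precision) with an optional JSON sidecar.

    Values are printed with 17 significant digits, so reading the TSV back
    reproduces the floats exactly. The sidecar is written next to the TSV
    with extension ``.json`` and sorted keys for diffability.
    """
    path_tsv = Path(path_tsv)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with path_tsv.open("w") as fh:
        fh.write(f"{x_name}\t{y_name}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.17g}\t{yi:.17g}\n")
    if sidecar is not None:
        side = path_tsv.with_suffix(".json")
        side.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_curve(path_tsv: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read back a curve TSV written by :func:`write_curve`."""
    df = pd.read_csv(path_tsv, sep="\t", float_precision="round_trip")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _dataset_for_matrix(cm: ConfusionMatrix) -> ScoredDataset:
    """A dataset whose confusion matrix at FIXTURE_THRESHOLD equals ``cm``.

    Predicted positives get distinct scores above the threshold, predicted
    negatives distinct scores below it.
    """
    n_above = cm.tp + cm.fp
    n_below = cm.fn + cm.tn
    above = np.linspace(0.95, 0.55, n_above)
    below = np.linspace(0.45, 0.05, n_below)
    scores = np.concatenate([above, below])
    labels = np.concatenate(
        [
            np.ones(cm.tp, dtype=bool),
            np.zeros(cm.fp, dtype=bool),
            np.ones(cm.fn, dtype=bool),
            np.zeros(cm.tn, dtype=bool),
        ]
    )
    return ScoredDataset(scores, labels, np.zeros(len(scores), dtype=bool))


def generate_fixture(kind: str, seed: int = 0) -> ScoredDataset:
    """Built-in worked-example datasets.

    ``table2_balanced`` / ``table2_imbalanced`` produce 20-instance
    datasets whose confusion matrix at threshold ``FIXTURE_THRESHOLD``
    is exactly (TP, FN, FP, TN) = (6, 4, 4, 6) and (3, 2, 6, 9).

    ``worked_example`` produces the 20-instance curve-construction
    example: 10 positives and 10 negatives, distinct descending scores at
    the top and middle of the ranking, one mixed tie block of 6 instances
    (3 positives, 3 negatives sharing one score) spanning curve points
    6-12, and five unscored instances at the bottom, so that tie policies,
    the convex hull (vertices at points 0, 2, 6, 13, 15 and 20) and the
    missing-score default all have visible effect. The score values are
    synthetic; only the rank structure matters.

    ``seed`` is accepted for interface uniformity; the fixtures are
    deterministic.
    """
    if kind == "table2_balanced":
        return _dataset_for_matrix(ConfusionMatrix(tp=6, fn=4, fp=4, tn=6))
    if kind == "table2_imbalanced":
        return _dataset_for_matrix(ConfusionMatrix(tp=3, fn=2, fp=6, tn=9))
    if kind == "worked_example":
        # descending ranks 1..15 scored, 16..20 missing
        scores: list[Optional[float]] = [
            0.95, 0.90, 0.85, 0.80, 0.75, 0.70,  # ranks 1-6, distinct
            0.60, 0.60, 0.60, 0.60, 0.60, 0.60,  # ranks 7-12, tie block
            0.50, 0.45, 0.40,                     # ranks 13-15, distinct
            None, None, None, None, None,         # ranks 16-20, unscored
        ]
        labels = [
            1, 1, 0, 1, 1, 1,        # 5 pos, 1 neg
            1, 1, 1, 0, 0, 0,        # tie block: 3 pos, 3 neg
            1, 0, 1,                 # 2 pos, 1 neg
            0, 0, 0, 0, 0,           # unscored: 5 neg
        ]
        return ScoredDataset.from_items(scores, labels)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
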