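"""Random-sampling simulator of classifier performance levels.

Scores are drawn independently for positives and negatives from
level-specific distributions, so that the overlap between the two score
clouds dials the classifier's quality:

=========  ================  ================  =======================
Level      Positives         Negatives         Character
=========  ================  ================  =======================
Rand       N(0, 1)           N(0, 1)           random, AUC 0.5
ER-        Beta(4, 1)        Beta(1, 1)        good overall (AUC 0.8)
                                               but poor early retrieval
ER+        Beta(1, 1)        Beta(1, 4)        AUC 0.8 with good early
                                               retrieval
Excel      N(3, 1)           N(0, 1)           excellent (AUC ~ 0.983)
Perf       constant 1        constant 0        perfect, AUC 1
=========  ================  ================  =======================

One simulation round samples a dataset, ranks it (ties keep input order),
sweeps thresholds, and evaluates the requested curve families; rounds are
repeated and the curves aggregated per x-axis bin by the median, the
standard protocol for showing a "typical" curve rather than a mean that
smears over crossing curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .costcurve import nec_line
from .croc import CrocCurve, MagnifierConfig, croc_curve
from .prc import auc_prc, densify_pr, prc_points
from .roc import auc_trapezoid, roc_points
from .scores import ScoredDataset, ThresholdSweep, TiePolicy, sweep_confusions

_LEVEL_ALIASES = {
    "rand": "Rand",
    "random": "Rand",
    "er-": "ER-",
    "erminus": "ER-",
    "er_minus": "ER-",
    "er+": "ER+",
    "erplus": "ER+",
    "er_plus": "ER+",
    "excel": "Excel",
    "excellent": "Excel",
    "perf": "Perf",
    "perfect": "Perf",
}

LEVELS = ("Rand", "ER-", "ER+", "Excel", "Perf")
FAMILIES = ("roc", "prc", "croc", "cc")


def canonical_level(level: str) -> str:
    try:
        return _LEVEL_ALIASES[level.lower()]
    except KeyError:
        raise ValueError(f"unknown performance level: {level!r}; choose from {LEVELS}")


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation design: level, sample sizes, iterations, bins, seed."""

    level: str
    n_pos: int = 1000
    n_neg: int = 1000
    iterations: int = 1000
    bins: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", canonical_level(self.level))
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass(frozen=True)
class AggregatedCurves:
    """Binned-median curves and median AUCs across iterations.

    ``x`` holds the bin centers shared by all families; ``median_curves``
    maps family -> median y per bin; ``auc_samples`` keeps each
    iteration's AUC so callers can inspect spread; ``median_auc`` is its
    median. For the cost-curve family the "AUC" slot stores the area under
    the expected-cost envelope (lower is better).
    """

    x: np.ndarray
    median_curves: dict
    median_auc: dict
    auc_samples: dict
    spec: SimulationSpec
    params: dict = field(default_factory=dict)


def sample_scores(
    level: str, n_pos: int, n_neg: int, rng: np.random.Generator
) -> ScoredDataset:
    """Draw one scored dataset for a performance level.

    Positive scores are drawn first, then negatives, so the instance
    order (and hence the tie-rank rule) is reproducible from the RNG
    state alone.
    """
    level = canonical_level(level)
    if level == "Rand":
        pos = rng.normal(0.0, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
    elif level == "ER-":
        pos = rng.beta(4.0, 1.0, n_pos)
        neg = rng.beta(1.0, 1.0, n_neg)
    elif level == "ER+":
        pos = rng.beta(1.0, 1.0, n_pos)
        neg = rng.beta(1.0, 4.0, n_neg)
    elif level == "Excel":
        pos = rng.normal(3.0, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
    else:  # Perf
        pos = np.ones(n_pos)
        neg = np.zeros(n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    return ScoredDataset(scores, labels, np.zeros(n_pos + n_neg, dtype=bool))


def bin_centers(bins: int) -> np.ndarray:
    """Centers of ``bins`` equal-width bins spanning [0, 1]."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return (np.arange(bins) + 0.5) / bins


def bin_median(
    xy_per_iteration: Sequence[tuple[np.ndarray, np.ndarray]], bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Median curve over iterations on a common bin grid.

    Each iteration's curve is evaluated at the centers of ``bins``
    equal-width x bins by linear interpolation along its own points, then
    the per-center median is taken across iterations (even counts use the
    mean of the two middle values, the numpy convention).
    """
    centers = bin_centers(bins)
    ys = np.vstack([np.interp(centers, np.asarray(x), np.asarray(y))
                    for x, y in xy_per_iteration])
    return centers, np.median(ys, axis=0)


def fp_count_at_tpr(sweep: ThresholdSweep, tpr: float) -> int:
    """False-positive count at the first sweep element reaching the given TPR."""
    if not (0 <= tpr <= 1):
        raise ValueError("tpr must lie in [0, 1]")
    target_tp = int(np.ceil(tpr * sweep.n_pos))
    idx = int(np.searchsorted(sweep.tp, target_tp, side="left"))
    return int(sweep.fp[idx])


def _iteration_rngs(seed: int, iterations: int) -> list[np.random.Generator]:
    # one child stream per iteration: results do not depend on evaluation order
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(iterations)]


def median_fp_at_tpr(spec: SimulationSpec, tpr: float = 0.5,
                     tie_policy: TiePolicy = "average") -> float:
    """Median over iterations of the FP count at a fixed TPR.

    E.g. for the ER- level at 1000/1000 the threshold reaching 500 true
    positives admits a median of about 160 false positives.
    """
    counts = []
    for rng in _iteration_rngs(spec.seed, spec.iterations):
        ds = sample_scores(spec.level, spec.n_pos, spec.n_neg, rng)
        sweep = sweep_confusions(ds, tie_policy=tie_policy)
        counts.append(fp_count_at_tpr(sweep, tpr))
    return float(np.median(counts))


def run_simulation(
    spec: SimulationSpec,
    families: Iterable[str] = FAMILIES,
    tie_policy: TiePolicy = "average",
    magnifier: MagnifierConfig = MagnifierConfig(),
    steps_per_tp: int = 1,
    croc_points_per_segment: int = 20,
) -> AggregatedCurves:
    """Repeat sample -> rank -> sweep -> evaluate, and aggregate by medians.

    Per iteration each requested family's curve is evaluated on the shared
    bin-center grid — linear interpolation along ROC and CROC polylines,
    the non-linear count interpolation for PRC, and the line-envelope
    minimum for the cost curve — and the per-bin median across iterations
    is reported together with the median AUC. Fully deterministic for a
    fixed seed: each iteration draws from its own child stream of the root
    seed.
    """
    families = list(families)
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown curve families: {sorted(unknown)}")
    centers = bin_centers(spec.bins)
    per_family_y: dict[str, list[np.ndarray]] = {f: [] for f in families}
    per_family_auc: dict[str, list[float]] = {f: [] for f in families}

    for rng in _iteration_rngs(spec.seed, spec.iterations):
        ds = sample_scores(spec.level, spec.n_pos, spec.n_neg, rng)
        sweep = sweep_confusions(ds, tie_policy=tie_policy)
        roc = roc_points(sweep) if ({"roc", "croc"} & set(families)) else None
        if "roc" in families:
            per_family_y["roc"].append(np.interp(centers, roc.fpr, roc.tpr))
            per_family_auc["roc"].append(auc_trapezoid(roc))
        if "prc" in families:
            pr = prc_points(sweep)
            rec, prec = densify_pr(pr, steps_per_tp=steps_per_tp)
            per_family_y["prc"].append(np.interp(centers, rec, prec))
            per_family_auc["prc"].append(float(np.trapezoid(prec, rec)))
        if "croc" in families:
            cr: CrocCurve = croc_curve(roc, magnifier,
                                       points_per_segment=croc_points_per_segment)
            per_family_y["croc"].append(np.interp(centers, cr.x, cr.y))
            per_family_auc["croc"].append(cr.auc)
        if "cc" in families:
            fpr = sweep.fp / sweep.n_neg
            fnr = sweep.fn / sweep.n_pos
            nec = fnr[:, None] * centers[None, :] + fpr[:, None] * (1.0 - centers[None, :])
            env = nec.min(axis=0)
            per_family_y["cc"].append(env)
            per_family_auc["cc"].append(float(np.trapezoid(env, centers)))

    median_curves = {f: np.median(np.vstack(per_family_y[f]), axis=0) for f in families}
    auc_samples = {f: np.array(per_family_auc[f]) for f in families}
    median_auc = {f: float(np.median(auc_samples[f])) for f in families}
    return AggregatedCurves(
        x=centers,
        median_curves=median_curves,
        median_auc=median_auc,
        auc_samples=auc_samples,
        spec=spec,
        params={
            "tie_policy": tie_policy,
            "alpha": magnifier.alpha,
            "steps_per_tp": steps_per_tp,
        },
    )
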