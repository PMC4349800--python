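import numpy as np
import pytest

from curveval import (
    PrSegment,
    ScoredDataset,
    auc_prc,
    interpolate_pr,
    pr_to_roc,
    prc_baseline,
    prc_points,
    roc_to_pr,
    sample_scores,
    sweep_confusions,
)
from curveval.prc import densify_pr

from helpers import auc_prc_bruteforce, random_dataset


def test_prc_point_from_imbalanced_matrix():
    # tp=3, fp=6 with P=5 renders as (recall 0.6, precision 1/3)
    ds = ScoredDataset.from_items(
        [0.9, 0.8, 0.7, 0.6, 0.55, 0.53, 0.52, 0.51, 0.505] + [0.3, 0.2] + [0.1] * 9,
        [1, 1, 1, 0, 0, 0, 0, 0, 0] + [1, 1] + [0] * 9,
    )
    curve = prc_points(sweep_confusions(ds))
    pts = set(zip(np.round(curve.recall, 6), np.round(curve.precision, 6)))
    assert (0.6, round(1 / 3, 6)) in pts


def test_perfect_separation_precision_one_everywhere():
    ds = ScoredDataset.from_items([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    curve = prc_points(sweep_confusions(ds))
    at_full = curve.precision[curve.recall == 1.0]
    assert np.all(curve.precision[curve.recall <= 1.0][:2] == 1.0)
    assert at_full.max() == 1.0
    assert auc_prc(curve) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "n_neg, expected", [(1000, 0.757), (10000, 0.238)]
)
def test_roc_point_to_precision_balanced_vs_imbalanced(n_neg, expected):
    # the same ROC point (fpr 0.16, tpr 0.5) yields very different precision
    # under 1:1 and 1:10 class ratios
    rec, prec = roc_to_pr((0.16, 0.5), n_pos=1000, n_neg=n_neg)
    assert rec == pytest.approx(0.5)
    assert prec == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize(
    "pn, expected",
    [((10, 10), 0.5), ((1000, 10000), 0.09), ((5, 0), 1.0)],
)
def test_prc_baseline(pn, expected):
    assert round(prc_baseline(*pn), 2) == expected


def test_prc_baseline_requires_positives():
    with pytest.raises(ValueError):
        prc_baseline(0, 10)


def test_interpolation_formula_endpoints_and_midpoint():
    seg = PrSegment(tp_a=2, fp_a=0, tp_b=4, fp_b=2, n_pos=4)
    assert interpolate_pr(seg, 0)[1] == pytest.approx(2 / 2)
    assert interpolate_pr(seg, 2)[1] == pytest.approx(4 / 6)
    # one extra TP at a local skew of 1 FP per TP: counts (3, 1)
    rec, prec = interpolate_pr(seg, 1)
    assert prec == pytest.approx(3 / 4)
    assert rec == pytest.approx(3 / 4)


def test_interpolation_rejects_vertical_segments_and_bad_x():
    with pytest.raises(ValueError):
        PrSegment(tp_a=3, fp_a=1, tp_b=3, fp_b=5, n_pos=10)
    seg = PrSegment(tp_a=0, fp_a=0, tp_b=2, fp_b=2, n_pos=5)
    with pytest.raises(ValueError):
        interpolate_pr(seg, 3)


def test_interpolated_precision_equals_direct_count_evaluation(rng):
    """At every integer x the formula must reproduce tp/(tp+fp) computed
    from the interpolated counts themselves."""
    for _ in range(20):
        tp_a = int(rng.integers(0, 10))
        dtp = int(rng.integers(1, 8))
        fp_a = int(rng.integers(0, 10))
        dfp = int(rng.integers(0, 12))
        seg = PrSegment(tp_a, fp_a, tp_a + dtp, fp_a + dfp, n_pos=tp_a + dtp)
        for x in range(dtp + 1):
            tp = tp_a + x
            fp = fp_a + dfp * x / dtp
            if tp + fp == 0:
                continue
            assert interpolate_pr(seg, x)[1] == pytest.approx(tp / (tp + fp))


def test_interpolant_bounded_by_dense_count_evaluation():
    seg = PrSegment(tp_a=1, fp_a=4, tp_b=7, fp_b=6, n_pos=7)
    xs = np.linspace(0, 6, 601)
    prec = np.array([interpolate_pr(seg, x)[1] for x in xs])
    # dense brute-force evaluation from interpolated counts
    dense = (seg.tp_a + xs) / (seg.tp_a + xs + seg.fp_a + seg.skew * xs)
    assert prec.min() >= dense.min() - 1e-12
    assert prec.max() <= dense.max() + 1e-12
    # the interpolant is monotone along the segment (here: rising precision)
    assert np.all(np.diff(prec) > -1e-12)


def test_auc_prc_matches_exhaustive_oracle(rng):
    for _ in range(25):
        ds = random_dataset(rng, int(rng.integers(1, 8)), int(rng.integers(1, 8)),
                            tie_fraction=0.3)
        curve = prc_points(sweep_confusions(ds))
        assert auc_prc(curve, steps_per_tp=1) == pytest.approx(auc_prc_bruteforce(ds))


def test_auc_prc_finer_grid_converges(rng):
    ds = random_dataset(rng, 20, 30)
    curve = prc_points(sweep_confusions(ds))
    coarse = auc_prc(curve, steps_per_tp=1)
    fine = auc_prc(curve, steps_per_tp=16)
    assert abs(coarse - fine) < 5e-3


def test_random_scores_auc_prc_approaches_baseline(rng):
    """Large-sample random scores: AUC(PRC) converges to P/(P+N).

    Tolerance is three Monte-Carlo standard errors (sd ~ 0.0026 at this
    design, measured over repeated draws)."""
    ds = sample_scores("Rand", 1000, 10000, rng)
    curve = prc_points(sweep_confusions(ds))
    assert auc_prc(curve) == pytest.approx(prc_baseline(1000, 10000), abs=0.008)


def test_roc_pr_round_trip_identity(rng):
    for _ in range(10):
        ds = random_dataset(rng, int(rng.integers(1, 12)), int(rng.integers(1, 12)),
                            tie_fraction=0.3)
        sweep = sweep_confusions(ds)
        for tp, fp in zip(sweep.tp, sweep.fp):
            if tp + fp == 0:
                continue
            fpr, tpr = fp / ds.n_neg, tp / ds.n_pos
            rec, prec = roc_to_pr((fpr, tpr), ds.n_pos, ds.n_neg)
            assert prec > 0 or tp == 0
            if prec > 0:
                back = pr_to_roc((rec, prec), ds.n_pos, ds.n_neg)
                assert back == pytest.approx((fpr, tpr), abs=1e-12)


def test_roc_to_pr_balanced_example():
    assert roc_to_pr((0.4, 0.6), 10, 10) == pytest.approx((0.6, 0.6))
    assert roc_to_pr((0.4, 0.6), 5, 15) == pytest.approx((0.6, 1 / 3))
    with pytest.raises(ValueError):
        roc_to_pr((0.0, 0.0), 10, 10)


def test_densified_curve_spans_recall_zero_to_one(rng):
    ds = random_dataset(rng, 6, 9, tie_fraction=0.3)
    curve = prc_points(sweep_confusions(ds))
    rec, prec = densify_pr(curve)
    assert rec[0] == 0.0 and rec[-1] == 1.0
    assert np.all(np.diff(rec) >= 0)
    assert np.all((prec >= 0) & (prec <= 1))
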