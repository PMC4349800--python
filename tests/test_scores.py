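import numpy as np
import pytest

from curveval import (
    ScoredDataset,
    apply_missing_default,
    auc_trapezoid,
    confusion_at_threshold,
    rank_scores,
    roc_points,
    sweep_confusions,
)
from curveval.scores import MissingScoreError

from helpers import pair_count_auc, random_dataset


@pytest.mark.parametrize(
    "scores, expected",
    [
        ([0.2, 0.9, 0.5], [1, 3, 2]),
        ([0.5, 0.5, 0.1], [2, 3, 1]),  # ties keep order of occurrence
        ([0.4, 0.4, 0.4, 0.4], [1, 2, 3, 4]),
    ],
)
def test_rank_scores(scores, expected):
    ds = ScoredDataset.from_items(scores, [1] * (len(scores) - 1) + [0])
    assert rank_scores(ds).tolist() == expected


def test_rank_requires_complete_scores():
    ds = ScoredDataset.from_items([0.5, None], [1, 0])
    with pytest.raises(MissingScoreError):
        rank_scores(ds)


def test_sweep_four_instance_path(four_instance_dataset):
    sweep = sweep_confusions(four_instance_dataset)
    assert sweep.tp.tolist() == [0, 1, 1, 2, 2]
    assert sweep.fp.tolist() == [0, 0, 1, 1, 2]
    assert auc_trapezoid(roc_points(sweep)) == pytest.approx(0.75)


@pytest.mark.parametrize("policy, auc", [("upper", 1.0), ("lower", 0.75), ("average", 0.875)])
def test_tie_policies_bound_the_block(tie_block_dataset, policy, auc):
    sweep = sweep_confusions(tie_block_dataset, tie_policy=policy)
    assert auc_trapezoid(roc_points(sweep)) == pytest.approx(auc)


def test_perfect_separation_passes_through_corner():
    ds = ScoredDataset.from_items([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    curve = roc_points(sweep_confusions(ds))
    pts = set(zip(curve.fpr, curve.tpr))
    assert (0.0, 1.0) in pts


def test_sweep_conservation_and_endpoints(rng):
    for _ in range(10):
        ds = random_dataset(rng, rng.integers(1, 20), rng.integers(1, 20), tie_fraction=0.5)
        for policy in ("upper", "lower", "average"):
            sweep = sweep_confusions(ds, tie_policy=policy)
            assert np.all(sweep.tp + sweep.fn == ds.n_pos)
            assert np.all(sweep.fp + sweep.tn == ds.n_neg)
            assert sweep.tp[0] == sweep.fp[0] == 0
            assert sweep.fn[-1] == sweep.tn[-1] == 0


def test_average_policy_auc_is_mean_of_upper_and_lower(rng):
    """For a single mixed tie block the chord halves the upper/lower paths."""
    for _ in range(25):
        n_distinct = int(rng.integers(2, 8))
        block = int(rng.integers(2, 6))
        scores = list(np.sort(rng.uniform(0.5, 1.0, n_distinct))[::-1]) + [0.25] * block
        labels = list(rng.integers(0, 2, n_distinct + block))
        labels[0] = 1
        labels[-1] = 0
        ds = ScoredDataset.from_items(scores, labels)
        if ds.n_pos == 0 or ds.n_neg == 0:
            continue
        aucs = {
            pol: auc_trapezoid(roc_points(sweep_confusions(ds, tie_policy=pol)))
            for pol in ("upper", "lower", "average")
        }
        assert aucs["average"] == pytest.approx((aucs["upper"] + aucs["lower"]) / 2)


def test_score_sign_and_label_flip_mirrors_sweep(rng):
    for _ in range(10):
        ds = random_dataset(rng, rng.integers(1, 15), rng.integers(1, 15), tie_fraction=0.4)
        mirrored = ScoredDataset(-ds.scores, ~ds.labels, ds.missing.copy())
        a = sweep_confusions(ds, tie_policy="average")
        b = sweep_confusions(mirrored, tie_policy="average")
        assert b.tp.tolist() == a.tn[::-1].tolist()
        assert b.fp.tolist() == a.fn[::-1].tolist()


def test_average_sweep_auc_equals_pair_counting(rng):
    for _ in range(20):
        ds = random_dataset(rng, rng.integers(1, 25), rng.integers(1, 25), tie_fraction=0.5)
        auc = auc_trapezoid(roc_points(sweep_confusions(ds, tie_policy="average")))
        assert auc == pytest.approx(pair_count_auc(ds))


def test_missing_default_forms_terminal_tie_block():
    ds = ScoredDataset.from_items(
        [0.9, 0.8, 0.7, None, None], [1, 0, 1, 1, 0]
    )
    filled = apply_missing_default(ds)
    assert not filled.has_missing
    defaults = filled.scores[3:]
    assert np.all(defaults == defaults[0])
    assert defaults[0] < 0.7
    # identity on complete data
    assert apply_missing_default(filled) is filled


def test_missing_default_single_pair():
    ds = ScoredDataset.from_items([0.4, None], [1, 0])
    filled = apply_missing_default(ds)
    assert filled.scores[1] < 0.4


def test_all_missing_rejected():
    ds = ScoredDataset.from_items([None, None], [1, 0])
    with pytest.raises(ValueError):
        apply_missing_default(ds)


def test_sweep_rejects_missing_and_single_class():
    with pytest.raises(MissingScoreError):
        sweep_confusions(ScoredDataset.from_items([0.5, None], [1, 0]))
    with pytest.raises(ValueError):
        sweep_confusions(ScoredDataset.from_items([0.5, 0.4], [1, 1]))


def test_confusion_at_threshold_uses_geq_rule():
    ds = ScoredDataset.from_items([0.9, 0.5, 0.1], [1, 0, 1])
    cm = confusion_at_threshold(ds, 0.5)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 0)
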