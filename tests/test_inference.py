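"""Sliding-window enumeration and the four aggregation rules."""

import math

import numpy as np
import pytest

from petmri3d.inference import (
    SlidingWindowConfig,
    WindowScores,
    aggregate,
    classify_dataset,
    score_windows,
    window_starts,
)
from petmri3d.model import ModelConfig, build_model, forward
from petmri3d.training import Ensemble, FoldModel


def _brute_force_starts(depth, window, stride, tail):
    starts = [s for s in range(0, depth) if s % stride == 0 and s + window <= depth]
    if tail == "end_aligned" and starts and starts[-1] + window < depth:
        starts.append(depth - window)
    return starts


@pytest.mark.parametrize("depth,policy,expected", [
    (48, "floor", [0, 16]),
    (48, "end_aligned", [0, 16]),
    (32, "floor", [0]),
    (32, "end_aligned", [0]),
    (50, "floor", [0, 16]),
    (50, "end_aligned", [0, 16, 18]),
])
def test_window_starts_examples(depth, policy, expected):
    cfg = SlidingWindowConfig(window=32, stride=16, tail_policy=policy)
    assert list(window_starts(depth, cfg)) == expected


def test_window_starts_match_enumeration_for_study_depths():
    for policy in ("floor", "end_aligned"):
        cfg = SlidingWindowConfig(window=32, stride=16, tail_policy=policy)
        for depth in range(32, 67):
            assert list(window_starts(depth, cfg)) == _brute_force_starts(
                depth, 32, 16, policy
            ), (depth, policy)


def test_too_shallow_volume_raises():
    with pytest.raises(ValueError, match="window"):
        window_starts(30, SlidingWindowConfig())


# -- aggregation -------------------------------------------------------------

def _ws(probs):
    return WindowScores(starts=tuple(range(0, 16 * len(probs), 16)), probs=tuple(probs))


def test_average_median_weighted_majority_examples():
    assert aggregate(_ws([0.9, 0.8, 0.7]), "average", 0.5).score == pytest.approx(0.8)
    assert aggregate(_ws([0.2, 0.4, 0.9]), "median", 0.5).score == pytest.approx(0.4)
    # W=2: weights (1/3, 2/3)
    assert aggregate(_ws([0.9, 0.3]), "weighted", 0.5).score == pytest.approx(0.5)
    assert aggregate(_ws([0.6, 0.6, 0.4]), "majority", 0.5).decision == 1


def test_majority_tie_on_even_windows_is_negative():
    pred = aggregate(_ws([0.9, 0.1]), "majority", 0.5)
    assert pred.decision == 0
    assert math.isnan(pred.score)


def test_weighted_weights_sum_to_one_and_downweight_superior():
    from petmri3d.inference import _weights
    for n in range(1, 9):
        w = _weights(n)
        assert w.sum() == pytest.approx(1.0)
        assert (np.diff(w) > 0).all()  # inferior windows weigh more


def test_aggregation_scores_bounded_by_window_scores(rng):
    for _ in range(20):
        probs = rng.random(int(rng.integers(1, 7)))
        for method in ("average", "median", "weighted"):
            s = aggregate(_ws(probs), method, 0.5).score
            assert probs.min() - 1e-12 <= s <= probs.max() + 1e-12


def test_permutation_sensitivity():
    a, b = _ws([0.9, 0.2, 0.5]), _ws([0.5, 0.2, 0.9])
    for method in ("average", "median"):
        assert aggregate(a, method, 0.5).score == aggregate(b, method, 0.5).score
    assert aggregate(a, "weighted", 0.5).score != aggregate(b, "weighted", 0.5).score


def test_unknown_method_raises():
    with pytest.raises(ValueError, match="unknown"):
        aggregate(_ws([0.5]), "geometric", 0.5)


# -- ensemble scoring --------------------------------------------------------

@pytest.fixture(scope="module")
def identical_member_ensemble():
    cfg = ModelConfig(in_channels=1, stage_filters=(4, 8), dense_units=8, seed=0)
    return Ensemble(members=[FoldModel(model=build_model(cfg), threshold=0.5)
                             for _ in range(5)])


def test_identical_members_reduce_to_single_model(identical_member_ensemble):
    ens = identical_member_ensemble
    vol = np.random.default_rng(0).random((16, 16, 40, 1)).astype(np.float32)
    cfg = SlidingWindowConfig(window=32, stride=16)
    ws = score_windows(ens, vol, cfg)
    assert len(ws.starts) == 2
    direct = forward(ens.members[0].model, vol[:, :, 0:32, :])
    assert ws.probs[0] == pytest.approx(direct, rel=1e-6)
    assert all(0 < p < 1 for p in ws.probs)


def test_single_window_volume_equals_whole_volume_forward(identical_member_ensemble):
    ens = identical_member_ensemble
    vol = np.random.default_rng(1).random((16, 16, 32, 1)).astype(np.float32)
    ws = score_windows(ens, vol, SlidingWindowConfig())
    assert len(ws.probs) == 1
    assert ws.probs[0] == pytest.approx(forward(ens.members[0].model, vol), rel=1e-6)


def test_classify_dataset_two_window_average_equals_median(identical_member_ensemble):
    rng = np.random.default_rng(2)
    cases = [(f"c{i}", rng.random((16, 16, 48, 1)).astype(np.float32), i % 2)
             for i in range(6)]
    table, metrics = classify_dataset(identical_member_ensemble, cases,
                                      SlidingWindowConfig(window=32, stride=16))
    avg = table[table.method == "average"].set_index("case_id").score
    med = table[table.method == "median"].set_index("case_id").score
    # the median of two values is their mean
    np.testing.assert_allclose(avg, med, rtol=1e-12)
    assert math.isnan(metrics["majority"]["auc"])
    assert 0.0 <= metrics["average"]["auc"] <= 1.0
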