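import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretogen import (ObjectiveSpec, ScoreMatrix, desirability, dominates,
                       non_dominated_sort, normalize_px, pareto_reward,
                       rank_within_front, score_batch, ws_reward, ws_weights)
from paretogen.qsar import ToyOracle


# ---------------------------------------------------------------- normalize

@pytest.mark.parametrize("px,direction,expected", [
    (6.5, "high_affinity", 0.5),
    (3.0, "high_affinity", 0.0),
    (10.0, "high_affinity", 1.0),
    (3.0, "low_affinity", 1.0),
    (10.0, "low_affinity", 0.0),
    (12.0, "high_affinity", 1.0),   # clipped
    (1.0, "high_affinity", 0.0),    # clipped
])
def test_normalize_px_values(px, direction, expected):
    assert normalize_px(px, direction) == pytest.approx(expected, abs=1e-12)


@given(st.floats(3.0, 10.0), st.floats(3.0, 10.0))
def test_normalize_px_monotone_and_complementary(a, b):
    if a < b:
        assert normalize_px(a) <= normalize_px(b)
        assert normalize_px(a, "low_affinity") >= normalize_px(b, "low_affinity")
    assert normalize_px(a) + normalize_px(a, "low_affinity") == pytest.approx(1.0)


# --------------------------------------------------------------- score_batch

def test_score_batch_zeroes_invalid_and_flags_desired(objectives):
    m = score_batch(["C(", "c1ccccc1c1ccncc1N"], objectives)
    assert not m.valid[0] and (m.scores[0] == 0).all() and not m.desired[0]
    assert m.valid[1]


def test_desired_requires_strict_inequality_on_every_objective():
    matrix = ScoreMatrix(smiles=["a", "b"],
                         scores=np.array([[0.6, 0.5, 0.9], [0.6, 0.7, 0.9]]),
                         valid=np.array([True, True]),
                         desired=np.zeros(2, bool), thresholds=np.full(3, 0.5))
    desired = matrix.valid & (matrix.scores > matrix.thresholds).all(axis=1)
    assert list(desired) == [False, True]  # 0.5 is not > 0.5


def test_score_batch_requires_objectives():
    with pytest.raises(ValueError):
        score_batch(["CCO"], [])


def test_objective_spec_validates_direction_and_threshold():
    oracle = ToyOracle("aromatic_rings")
    with pytest.raises(ValueError):
        ObjectiveSpec(predictor=oracle, direction="sideways")
    with pytest.raises(ValueError):
        ObjectiveSpec(predictor=oracle, threshold=1.0)


# ------------------------------------------------------------- weighted sum

def test_ws_weights_worked_example():
    # obj1: 8 below / 2 above (r=4); obj2: 2 below / 8 above (r=0.25)
    scores = np.zeros((10, 2))
    scores[:2, 0] = 0.9
    scores[:8, 1] = 0.9
    w = ws_weights(scores, [0.5, 0.5])
    assert w == pytest.approx([0.941176, 0.058824], abs=1e-5)


def test_ws_weights_symmetric_objectives_get_equal_weight():
    scores = np.tile(np.linspace(0, 1, 10)[:, None], (1, 3))
    assert ws_weights(scores, 0.5) == pytest.approx([1 / 3] * 3)


@given(st.integers(2, 40), st.integers(2, 4), st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_ws_weights_sum_to_one_and_favor_harder_objectives(n, m, seed):
    rng = np.random.default_rng(seed)
    scores = rng.random((n, m))
    w = ws_weights(scores, 0.5)
    assert w.sum() == pytest.approx(1.0)
    above = (scores > 0.5).sum(axis=0)
    # strictly fewer molecules above threshold => weight at least as large
    for i in range(m):
        for j in range(m):
            if above[i] < above[j]:
                assert w[i] >= w[j]


@pytest.mark.parametrize("row,w,expected", [
    ((1, 1, 1), (0.2, 0.3, 0.5), 1.0),
    ((0, 0, 0), (0.2, 0.3, 0.5), 0.0),
    ((0.5, 1.0), (0.5, 0.5), 0.75),
])
def test_ws_reward_is_dot_product(row, w, expected):
    assert ws_reward(np.array(row), np.array(w))[0] == pytest.approx(expected)


def test_ws_reward_length_mismatch():
    with pytest.raises(ValueError):
        ws_reward(np.ones((1, 3)), np.ones(2))


# ------------------------------------------------------------- desirability

@pytest.mark.parametrize("r,t,expected", [
    (0.8, 0.5, 1.0),
    (0.25, 0.5, 0.5),
    (0.5, 0.5, 1.0),   # boundary uses the <= branch: 0.5/0.5
])
def test_desirability_piecewise(r, t, expected):
    assert desirability(r, t) == pytest.approx(expected)


# ----------------------------------------------------------------- dominance

def test_dominates_definition():
    assert dominates((0.9, 0.9), (0.5, 0.5))
    assert not dominates((0.8, 0.2), (0.2, 0.8))
    assert not dominates((0.2, 0.8), (0.8, 0.2))
    assert not dominates((0.5, 0.5), (0.5, 0.5))
    with pytest.raises(ValueError):
        dominates((1, 2), (1, 2, 3))


def _brute_force_fronts(vectors):
    """Independent O(n^2 m) oracle: repeatedly peel the non-dominated set."""
    remaining = list(range(len(vectors)))
    fronts_best_first = []
    while remaining:
        nd = [i for i in remaining
              if not any(dominates(vectors[j], vectors[i])
                         for j in remaining if j != i)]
        fronts_best_first.append(set(nd))
        remaining = [i for i in remaining if i not in nd]
    return fronts_best_first[::-1]


def test_non_dominated_sort_worked_example():
    vecs = np.array([(0.9, 0.9), (0.6, 0.6), (0.8, 0.2), (0.2, 0.8)])
    fronts = non_dominated_sort(vecs)
    assert [set(f) for f in fronts] == [{1, 2, 3}, {0}]


def test_non_dominated_sort_identical_vectors_single_front():
    fronts = non_dominated_sort(np.ones((5, 3)))
    assert [set(f) for f in fronts] == [{0, 1, 2, 3, 4}]


@given(st.integers(1, 50), st.integers(1, 4), st.integers(0, 10**6))
@settings(max_examples=200, deadline=None)
def test_non_dominated_sort_matches_brute_force_oracle(n, m, seed):
    rng = np.random.default_rng(seed)
    vecs = rng.random((n, m)).round(1)  # rounding forces ties
    fronts = non_dominated_sort(vecs)
    assert [set(f) for f in fronts] == _brute_force_fronts(vecs)
    assert sorted(i for f in fronts for i in f) == list(range(n))


# -------------------------------------------------------- within-front rank

def _bits(*on, size=16):
    fp = np.zeros(size, dtype=np.uint8)
    fp[list(on)] = 1
    return fp


def test_rank_within_front_singleton_identity():
    assert rank_within_front([3], [None, None, None, _bits(0)]) == [3]


def test_rank_within_front_outlier_first():
    # two near-identical molecules plus one sharing nothing: mean distances
    # are (outlier) 1.0 vs (pair) ~0.75 each — the outlier ranks on top
    fps = [_bits(0, 1, 2, 3), _bits(0, 1, 2, 4), _bits(8, 9, 10, 11)]
    assert rank_within_front([0, 1, 2], fps)[0] == 2


def test_rank_within_front_ties_keep_input_order():
    fps = [_bits(0), _bits(1), _bits(2)]  # all pairwise distance 1
    assert rank_within_front([0, 1, 2], fps) == [0, 1, 2]


# ------------------------------------------------------------ pareto reward

def _matrix(scores, valid=None, thresholds=0.5):
    scores = np.asarray(scores, float)
    n, m = scores.shape
    valid = np.ones(n, bool) if valid is None else np.asarray(valid)
    thresholds = np.full(m, thresholds)
    desired = valid & (scores > thresholds).all(axis=1)
    return ScoreMatrix(smiles=[f"m{i}" for i in range(n)], scores=scores,
                       valid=valid, desired=desired, thresholds=thresholds)


def _distinct_fps(n):
    return [_bits(i, size=max(16, n)) for i in range(n)]


def test_pareto_reward_two_undesired_two_desired():
    m = _matrix([[0.1, 0.1], [0.3, 0.3], [0.7, 0.7], [0.9, 0.9]])
    r = pareto_reward(m, _distinct_fps(4))
    assert sorted(r.rewards) == pytest.approx([0.25, 0.50, 0.75, 1.00])
    # dominance on desirability: the dominated undesired vector ranks lowest
    assert r.rewards[0] == pytest.approx(0.25)
    assert r.rewards[1] == pytest.approx(0.50)


def test_pareto_reward_all_desired():
    m = _matrix([[0.6, 0.6], [0.7, 0.7], [0.8, 0.8], [0.9, 0.9]])
    r = pareto_reward(m, _distinct_fps(4))
    assert sorted(r.rewards) == pytest.approx([0.625, 0.75, 0.875, 1.0])


def test_pareto_reward_single_undesired():
    m = _matrix([[0.1, 0.1]])
    r = pareto_reward(m, _distinct_fps(1))
    assert r.rewards[0] == pytest.approx(0.5)


def test_pareto_reward_invalid_molecules_get_lowest_ranks():
    m = _matrix([[0.0, 0.0], [0.4, 0.4], [0.9, 0.9]],
                valid=np.array([False, True, True]))
    r = pareto_reward(m, _distinct_fps(3))
    assert r.rank[0] == 1  # invalid pinned to the bottom
    assert r.rewards[0] == min(r.rewards)


@given(st.integers(2, 30), st.integers(2, 3), st.integers(0, 10**6))
@settings(max_examples=60, deadline=None)
def test_pareto_reward_intervals_and_monotonicity(n, m, seed):
    rng = np.random.default_rng(seed)
    mat = _matrix(rng.random((n, m)))
    r = pareto_reward(mat, _distinct_fps(n))
    und = ~mat.desired
    if und.any():
        assert (r.rewards[und] > 0).all() and (r.rewards[und] <= 0.5).all()
    if mat.desired.any():
        assert (r.rewards[mat.desired] > 0.5).all() and (r.rewards[mat.desired] <= 1.0).all()
        assert r.rewards[mat.desired].max() == pytest.approx(1.0)
    order = np.argsort(r.rank)
    assert (np.diff(r.rewards[order]) > 0).all()  # strictly monotone in k
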