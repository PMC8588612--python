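"""Multi-objective reward shaping: weighted-sum and Pareto-front schemes.

Each objective maps a predicted potency pX (clipped to [3, 10]) to a
normalized score R_i in [0, 1]; invalid molecules score 0 everywhere.  A
molecule is *desired* when every R_i strictly exceeds its threshold
(default 0.5, i.e. pX = 6.5 for a maximized objective).

Two schemes collapse the score vector to the scalar reward R* the policy
gradient consumes:

* **WS** — dynamic weighted sum.  Per objective, the ratio
  r_i = N_i^smaller / N_i^larger of molecules below vs above the threshold
  sets the weight w_i = r_i / Σ r_k, so harder objectives dominate the sum
  R* = Σ w_i R_i.

* **PF** — Pareto ranking on desirability-transformed scores
  (D_i = 1 if R_i > t_i else R_i / t_i): non-dominated sorting into fronts
  (worst front first), within-front ordering by mean Tanimoto distance
  (more distant = better), then a global 1-based rank k with every undesired
  molecule preceding every desired one.  Rewards are spread evenly:
  undesired fill (0, 0.5] via k / (2 N_undesired), desired fill (0.5, 1] via
  0.5 + (k − N_undesired) / (2 N_desired).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .features import N_BITS, fingerprint
from .metrics import tanimoto_distance
from .smiles import is_valid_smiles

PX_MIN, PX_MAX = 3.0, 10.0


@dataclass
class ObjectiveSpec:
    """One scoring target: a pX predictor, a direction, and a threshold."""

    predictor: Callable[[Sequence[str]], np.ndarray]
    direction: str = "high_affinity"   # or "low_affinity"
    threshold: float = 0.5
    name: str = ""

    def __post_init__(self):
        if self.direction not in ("high_affinity", "low_affinity"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


def normalize_px(px, direction: str = "high_affinity"):
    """Min-max map of pX over [3, 10] into [0, 1]; inverted for off-targets.

    high_affinity: (pX − 3) / 7  —  low_affinity: 1 − (pX − 3) / 7.
    Inputs are clipped to [3, 10] first (regressors can extrapolate).
    """
    px = np.clip(np.asarray(px, dtype=float), PX_MIN, PX_MAX)
    r = (px - PX_MIN) / (PX_MAX - PX_MIN)
    if direction == "low_affinity":
        r = 1.0 - r
    elif direction != "high_affinity":
        raise ValueError(f"unknown direction {direction!r}")
    return r if r.ndim else float(r)


@dataclass
class ScoreMatrix:
    """Per-molecule, per-objective normalized scores plus validity/desired flags."""

    smiles: list[str]
    scores: np.ndarray            # (n, m) R_i in [0, 1]; zero rows for invalid
    valid: np.ndarray             # (n,) bool
    desired: np.ndarray           # (n,) bool
    thresholds: np.ndarray        # (m,)
    canonical: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.smiles)


def score_batch(smiles: Sequence[str], objectives: Sequence[ObjectiveSpec]) -> ScoreMatrix:
    """Score every molecule on every objective.

    Invalid SMILES receive all-zero scores and are never desired; valid
    molecules are scored by each objective's predictor and normalized.
    """
    if not objectives:
        raise ValueError("objectives must be non-empty")
    smiles = list(smiles)
    n, m = len(smiles), len(objectives)
    valid = np.zeros(n, dtype=bool)
    canonical: list = [None] * n
    for i, smi in enumerate(smiles):
        ok, can = is_valid_smiles(smi)
        valid[i] = ok
        canonical[i] = can
    scores = np.zeros((n, m))
    vidx = np.nonzero(valid)[0]
    if len(vidx):
        vsmiles = [smiles[i] for i in vidx]
        for j, obj in enumerate(objectives):
            try:
                px = np.asarray(obj.predictor(vsmiles), dtype=float)
            except Exception as exc:  # noqa: BLE001 - reraise with context
                raise RuntimeError(
                    f"predictor failed for objective {obj.name or j}: {exc}") from exc
            if px.shape != (len(vsmiles),):
                raise RuntimeError(
                    f"objective {obj.name or j} returned shape {px.shape}, "
                    f"expected ({len(vsmiles)},)")
            scores[vidx, j] = normalize_px(px, obj.direction)
    thresholds = np.array([o.threshold for o in objectives])
    desired = valid & (scores > thresholds[None, :]).all(axis=1)
    return ScoreMatrix(smiles=smiles, scores=scores, valid=valid, desired=desired,
                       thresholds=thresholds, canonical=canonical)


# ---------------------------------------------------------------------------
# weighted-sum scheme
# ---------------------------------------------------------------------------

def ws_weights(scores: np.ndarray, thresholds) -> np.ndarray:
    """Dynamic objective weights from the below/above-threshold ratio.

    r_i = N_i^smaller / N_i^larger; if no molecule clears objective i the
    denominator is replaced by 1 (hardest objective keeps the largest finite
    weight).  Weights are normalized to sum to 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    thresholds = np.broadcast_to(np.asarray(thresholds, float), (scores.shape[1],))
    larger = (scores > thresholds[None, :]).sum(axis=0).astype(float)
    smaller = scores.shape[0] - larger
    r = smaller / np.where(larger == 0, 1.0, larger)
    if r.sum() == 0:  # every molecule clears every objective
        return np.full(scores.shape[1], 1.0 / scores.shape[1])
    return r / r.sum()


def ws_reward(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """R* = Σ_i w_i R_i (row-wise dot product)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if scores.shape[1] != weights.shape[0]:
        raise ValueError("weight/objective count mismatch")
    return scores @ weights


# ---------------------------------------------------------------------------
# Pareto-front scheme
# ---------------------------------------------------------------------------

def desirability(r, threshold):
    """D = 1 if R > t else R / t (credit above threshold is capped)."""
    r = np.asarray(r, dtype=float)
    t = np.asarray(threshold, dtype=float)
    if np.any(t <= 0):
        raise ValueError("thresholds must be positive")
    d = np.where(r > t, 1.0, r / t)
    return d if d.ndim else float(d)


def dominates(x, y) -> bool:
    """Strict Pareto dominance: x ≥ y everywhere and x > y somewhere."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    return bool((x >= y).all() and (x > y).any())


def non_dominated_sort(vectors: np.ndarray) -> list[list[int]]:
    """Partition row vectors into Pareto fronts, worst front first.

    Fast non-dominated sorting: compute each row's domination count and
    dominated set, peel off successive non-dominated layers, then reverse so
    the output runs from dominated (worst) to dominant (best) solutions.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = V.shape[0]
    if n == 0:
        raise ValueError("need at least one vector")
    ge = (V[:, None, :] >= V[None, :, :]).all(axis=2)
    gt = (V[:, None, :] > V[None, :, :]).any(axis=2)
    dom = ge & gt                      # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts_best_first: list[list[int]] = []
    remaining = n_dominators.copy()
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.nonzero((remaining == 0) & ~assigned)[0]
        fronts_best_first.append(list(current))
        assigned[current] = True
        for i in current:
            remaining[dom[i]] -= 1
    return fronts_best_first[::-1]


def rank_within_front(front: list[int], fingerprints: Sequence[np.ndarray],
                      ) -> list[int]:
    """Order one front by mean Tanimoto distance to its peers, descending.

    The most distant (most novel) member comes first; ties keep input order
    (stable sort).  Singleton fronts are returned unchanged.
    """
    if len(front) <= 1:
        return list(front)
    fps = [fingerprints[i] for i in front]
    k = len(front)
    mean_dist = np.zeros(k)
    for a in range(k):
        d = [tanimoto_distance(fps[a], fps[b]) for b in range(k) if b != a]
        mean_dist[a] = float(np.mean(d))
    order = np.argsort(-mean_dist, kind="stable")
    return [front[i] for i in order]


@dataclass
class ParetoRanking:
    """Front index, global rank k, and final reward per molecule."""

    front_index: np.ndarray     # (n,) worst front = 0
    rank: np.ndarray            # (n,) global 1-based k; larger = better
    rewards: np.ndarray         # (n,) R* in (0, 1]


def pareto_reward(matrix: ScoreMatrix,
                  fingerprints: Sequence[np.ndarray] | None = None) -> ParetoRanking:
    """Scalar rewards from the Pareto-front scheme.

    Dominance runs on desirability-transformed scores.  A global ordering is
    built from fronts (worst first) with within-front Tanimoto ranking, then
    stably partitioned so all undesired molecules precede all desired ones
    (invalid molecules are pinned to the very bottom).  The 1-based position
    k in that ordering sets the reward: undesired molecules fill (0, 0.5]
    with k / (2 N_und), desired fill (0.5, 1] with 0.5 + (k − N_und)/(2 N_des).
    """
    n = len(matrix)
    D = desirability(matrix.scores, matrix.thresholds[None, :])
    fronts = non_dominated_sort(D)
    if fingerprints is None:
        fingerprints = [fingerprint(c) if c is not None else np.zeros(N_BITS, dtype=np.uint8)
                        for c in (matrix.canonical if matrix.canonical else [None] * n)]
    front_index = np.empty(n, dtype=np.int64)
    ordering: list[int] = []   # worst ... best
    for fi, front in enumerate(fronts):
        ranked = rank_within_front(front, fingerprints)  # best first
        ordering.extend(reversed(ranked))                # append worst..best
        for i in front:
            front_index[i] = fi
    # stable partition: invalid first, then valid-undesired, then desired
    invalid = [i for i in ordering if not matrix.valid[i]]
    undesired = [i for i in ordering if matrix.valid[i] and not matrix.desired[i]]
    desired = [i for i in ordering if matrix.desired[i]]
    final_order = invalid + undesired + desired
    n_des = len(desired)
    n_und = n - n_des
    rank = np.empty(n, dtype=np.int64)
    for pos, i in enumerate(final_order, start=1):
        rank[i] = pos
    rewards = np.empty(n)
    for i in range(n):
        k = rank[i]
        if matrix.desired[i]:
            rewards[i] = 0.5 + (k - n_und) / (2.0 * n_des)
        else:
            rewards[i] = k / (2.0 * max(n_und, 1))
    return ParetoRanking(front_index=front_index, rank=rank, rewards=rewards)


def batch_reward(matrix: ScoreMatrix, scheme: str,
                 fingerprints: Sequence[np.ndarray] | None = None) -> np.ndarray:
    """Dispatch to the WS or PF scheme; invalid molecules get reward 0 in WS."""
    if scheme == "ws":
        w = ws_weights(matrix.scores, matrix.thresholds)
        return ws_reward(matrix.scores, w)
    if scheme == "pf":
        return pareto_reward(matrix, fingerprints).rewards
    raise ValueError(f"unknown scheme {scheme!r}; expected 'pf' or 'ws'")
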