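"""Policy-gradient training with the agent / crossover / mutation strategy.

Three generators with identical architecture drive exploration:

* the **agent** G_A — the only net whose parameters are updated (REINFORCE);
* the **crossover** net G_C — refreshed by copying G_A at iteration
  boundaries, blended with G_A during sampling;
* the **mutation** net G_M — frozen at the pretrained state, injecting
  off-policy tokens with probability ε per step.

At every token position a uniform draw u decides the sampling policy: u > ε
uses the combination of G_A and G_C (arithmetic mean of their per-step
distributions by default), u ≤ ε uses G_M.  An *iteration* ends when the
desirability of molecules sampled from G_A alone stops improving for a
configured number of epochs; training stops once an iteration fails to beat
the previous iteration's best desired fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .generator import GeneratorNet, SampleBatch
from .nnet import Adam
from .rewards import ObjectiveSpec, batch_reward, score_batch


@dataclass
class ExplorerConfig:
    epsilon: float = 1e-2            # per-step mutation rate
    batch_size: int = 64
    lr: float = 1e-3
    plateau_patience: int = 3        # epochs without desirability improvement
    max_iterations: int = 20
    max_epochs: int = 500            # overall safety cap
    eval_sample_size: int = 1000     # G_A-only sample for plateau detection
    mix: str = "arithmetic"          # or "geometric"
    seed: int = 0
    track_param_hashes: bool = False  # record per-epoch net digests in the log

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.mix not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown mix {self.mix!r}")


def mixed_step_distribution(p_agent: np.ndarray, p_crossover: np.ndarray,
                            p_mutation: np.ndarray, epsilon: float,
                            rng: np.random.Generator,
                            mix: str = "arithmetic") -> np.ndarray:
    """Combine the three nets' per-step distributions.

    One uniform draw per sequence decides between the G_A/G_C combination
    (u > ε) and G_M (u ≤ ε); rows are renormalized to sum to one.
    """
    if not (p_agent.shape == p_crossover.shape == p_mutation.shape):
        raise ValueError("distribution shape mismatch (vocabulary mismatch?)")
    if mix == "arithmetic":
        combo = 0.5 * (p_agent + p_crossover)
    else:
        combo = np.sqrt(p_agent * p_crossover)
    combo = combo / combo.sum(axis=1, keepdims=True)
    if epsilon <= 0.0:
        return combo
    u = rng.random(p_agent.shape[0])
    use_mutation = u <= epsilon
    return np.where(use_mutation[:, None], p_mutation, combo)


class MixedPolicy:
    """Step function sampling from the ε-mixed three-net policy."""

    def __init__(self, agent: GeneratorNet, crossover: GeneratorNet,
                 mutation: GeneratorNet, epsilon: float,
                 rng: np.random.Generator, mix: str = "arithmetic"):
        if not (agent.vocab.tokens == crossover.vocab.tokens == mutation.vocab.tokens):
            raise ValueError("the three nets must share one vocabulary")
        self.agent, self.crossover, self.mutation = agent, crossover, mutation
        self.epsilon = epsilon
        self.rng = rng
        self.mix = mix

    def step(self, tokens: np.ndarray, states):
        if states is None:
            n = len(tokens)
            states = (self.agent.net.init_state(n), self.crossover.net.init_state(n),
                      self.mutation.net.init_state(n))
        sa, sc, sm = states
        pa, sa = self.agent.net.step(tokens, sa)
        pc, sc = self.crossover.net.step(tokens, sc)
        pm, sm = self.mutation.net.step(tokens, sm)
        probs = mixed_step_distribution(pa, pc, pm, self.epsilon, self.rng, self.mix)
        return probs, (sa, sc, sm)


def sample_mixed(agent: GeneratorNet, crossover: GeneratorNet, mutation: GeneratorNet,
                 n: int, epsilon: float, rng: np.random.Generator,
                 mix: str = "arithmetic") -> SampleBatch:
    """Sample n sequences from the ε-mixed policy (decoded via the agent's vocab)."""
    policy = MixedPolicy(agent, crossover, mutation, epsilon, rng, mix)
    return agent.sample(n, rng=rng, step_fn=policy.step)


def policy_gradient_update(agent: GeneratorNet, token_ids: Sequence[np.ndarray],
                           rewards: np.ndarray, optimizer: Adam) -> float:
    """One REINFORCE step:  maximize  J(θ) = Σ_b R*_b Σ_t log G(y_t | y_<t).

    Implemented as Adam descent on the reward-weighted NLL (weights R*_b / B),
    whose gradient is exactly −∇J/B.  Returns the batch-mean objective J.
    """
    rewards = np.asarray(rewards, dtype=float)
    if len(token_ids) != len(rewards):
        raise ValueError("one reward per sequence required")
    B = len(token_ids)
    end = agent.vocab.end_index
    go = agent.vocab.go_index
    T = max(1, max(len(s) for s in token_ids))
    inputs = np.full((B, T), end, dtype=np.int64)
    targets = np.full((B, T), end, dtype=np.int64)
    mask = np.zeros((B, T))
    for b, seq in enumerate(token_ids):
        L = len(seq)
        inputs[b, 0] = go
        if L > 1:
            inputs[b, 1:L] = seq[:-1]
        targets[b, :L] = seq
        mask[b, :L] = 1.0
    loss, grads = agent.net.loss_and_grads(inputs, targets, mask,
                                           seq_weights=rewards / B)
    optimizer.step(grads)
    return -loss  # J / B


@dataclass
class TrainerState:
    """Bookkeeping across the RL run (returned alongside the trained agent)."""

    epoch_log: list = field(default_factory=list)
    iteration_log: list = field(default_factory=list)
    stopped_reason: str = ""


class RLAbortError(RuntimeError):
    pass


def train_rl(agent: GeneratorNet, crossover: GeneratorNet, mutation: GeneratorNet,
             objectives: Sequence[ObjectiveSpec], scheme: str = "pf",
             config: ExplorerConfig | None = None) -> TrainerState:
    """Run the full RL loop, updating ``agent`` in place.

    Per epoch: sample a batch from the ε-mixed policy, score it on every
    objective, collapse scores to scalar rewards under the chosen scheme
    ('pf' or 'ws'), take one policy-gradient step on G_A, then measure the
    desired fraction of a G_A-only sample for plateau detection.  G_C is
    refreshed from G_A at iteration boundaries; G_M never changes.  Aborts
    when five consecutive epochs produce no valid molecule.
    """
    cfg = config or ExplorerConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(agent.net.params, lr=cfg.lr)
    state = TrainerState()

    prev_iter_best = -np.inf
    iter_best = -np.inf
    epoch_best = -np.inf
    stall = 0
    iteration = 0
    invalid_streak = 0
    epoch = 0
    while epoch < cfg.max_epochs and iteration < cfg.max_iterations:
        epoch += 1
        batch = sample_mixed(agent, crossover, mutation, cfg.batch_size,
                             cfg.epsilon, rng, cfg.mix)
        if not batch.valid.any():
            invalid_streak += 1
            if invalid_streak >= 5:
                raise RLAbortError(
                    "no valid molecules in 5 consecutive epochs; the generator "
                    "has collapsed — check pretraining or lower the learning rate")
            continue
        invalid_streak = 0
        matrix = score_batch(batch.smiles, objectives)
        rewards = batch_reward(matrix, scheme)
        j_value = policy_gradient_update(agent, batch.token_ids, rewards, opt)

        eval_batch = agent.sample(cfg.eval_sample_size, rng=rng)
        eval_matrix = score_batch(eval_batch.smiles, objectives)
        desired_frac = float(eval_matrix.desired.mean())
        validity = float(eval_batch.valid.mean())
        uniq = len({c for c in eval_batch.canonical if c}) / len(eval_batch)
        entry = {
            "epoch": epoch, "iteration": iteration,
            "validity": validity, "desirability": desired_frac,
            "uniqueness": uniq, "mean_reward": float(np.mean(rewards)),
            "objective_j": float(j_value),
        }
        if cfg.track_param_hashes:
            entry["agent_hash"] = agent.param_hash()
            entry["crossover_hash"] = crossover.param_hash()
            entry["mutation_hash"] = mutation.param_hash()
        state.epoch_log.append(entry)
        iter_best = max(iter_best, desired_frac)
        if desired_frac > epoch_best:
            epoch_best = desired_frac
            stall = 0
        else:
            stall += 1
        if stall >= cfg.plateau_patience:
            # iteration boundary
            state.iteration_log.append({"iteration": iteration,
                                        "best_desirability": iter_best,
                                        "end_epoch": epoch})
            if iter_best <= prev_iter_best:
                state.stopped_reason = "no improvement over previous iteration"
                return state
            prev_iter_best = iter_best
            crossover.net.load_params_from(agent.net)
            iteration += 1
            iter_best = -np.inf
            epoch_best = -np.inf
            stall = 0
    state.stopped_reason = "epoch or iteration cap reached"
    return state
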