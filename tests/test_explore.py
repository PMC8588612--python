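import numpy as np
import pytest

from paretogen import (ExplorerConfig, GeneratorNet, mixed_step_distribution,
                       policy_gradient_update, sample_mixed, train_rl)
from paretogen.explore import MixedPolicy, RLAbortError
from paretogen.nnet import Adam
from paretogen.smiles import Vocabulary


def _three_nets(vocab, seed=0):
    mk = lambda s: GeneratorNet(vocab, emb_dim=8, hidden_dim=12, n_layers=1,
                                max_len=40, seed=s)
    return mk(seed), mk(seed + 1), mk(seed + 2)


# ------------------------------------------------------ mixed distribution

def test_epsilon_zero_never_consults_mutation_net(rng):
    pa = np.array([[0.7, 0.3]])
    pc = np.array([[0.1, 0.9]])
    pm = np.array([[1.0, 0.0]])
    out = mixed_step_distribution(pa, pc, pm, epsilon=0.0, rng=rng)
    assert out[0] == pytest.approx([0.4, 0.6])


def test_epsilon_one_always_uses_mutation_net(rng):
    pa = np.array([[0.7, 0.3]])
    pm = np.array([[0.0, 1.0]])
    out = mixed_step_distribution(pa, pa, pm, epsilon=1.0, rng=rng)
    assert out == pytest.approx(pm)


def test_identical_agent_and_crossover_reduce_to_agent(rng):
    pa = np.array([[0.25, 0.25, 0.5]])
    pm = np.ones((1, 3)) / 3
    out = mixed_step_distribution(pa, pa, pm, epsilon=0.0, rng=rng)
    assert out == pytest.approx(pa)


def test_distribution_shape_mismatch_is_an_error(rng):
    with pytest.raises(ValueError):
        mixed_step_distribution(np.ones((1, 3)), np.ones((1, 3)),
                                np.ones((1, 4)), 0.5, rng)


def test_vocabulary_mismatch_is_an_error(vocab):
    a, c, _ = _three_nets(vocab)
    other = GeneratorNet(Vocabulary.from_tokens(["C"]), emb_dim=8,
                         hidden_dim=12, n_layers=1, seed=0)
    with pytest.raises(ValueError):
        MixedPolicy(a, c, other, 0.1, np.random.default_rng(0))


def test_epsilon_zero_equals_plain_agent_sampling(vocab):
    """With ε=0 and G_C == G_A the mixed policy is exactly G_A (v1 reduction)."""
    agent, _, mutation = _three_nets(vocab)
    crossover = agent.clone()
    mixed = sample_mixed(agent, crossover, mutation, 10, epsilon=0.0,
                         rng=np.random.default_rng(5))
    plain = agent.sample(10, rng=np.random.default_rng(5))
    assert mixed.smiles == plain.smiles


def test_nonzero_epsilon_changes_samples(vocab):
    agent, crossover, mutation = _three_nets(vocab)
    a = sample_mixed(agent, crossover, mutation, 30, epsilon=0.0,
                     rng=np.random.default_rng(3))
    b = sample_mixed(agent, crossover, mutation, 30, epsilon=0.5,
                     rng=np.random.default_rng(3))
    assert a.smiles != b.smiles


# ------------------------------------------------------------ policy gradient

def test_zero_rewards_leave_parameters_unchanged(tiny_generator):
    gen = tiny_generator
    opt = Adam(gen.net.params, lr=0.1)
    batch = gen.sample(8, rng=np.random.default_rng(0))
    before = gen.param_hash()
    j = policy_gradient_update(gen, batch.token_ids, np.zeros(8), opt)
    assert gen.param_hash() == before
    assert j == 0.0


def test_reward_one_increases_sequence_likelihood(tiny_generator):
    gen = tiny_generator
    batch = gen.sample(1, rng=np.random.default_rng(1))
    seq = batch.token_ids[:1]
    before = gen.sequence_log_likelihood(seq)[0]
    opt = Adam(gen.net.params, lr=1e-3)
    policy_gradient_update(gen, seq, np.array([1.0]), opt)
    after = gen.sequence_log_likelihood(seq)[0]
    assert after > before


def test_reward_count_mismatch(tiny_generator):
    with pytest.raises(ValueError):
        policy_gradient_update(tiny_generator, [np.array([2, 1])],
                               np.ones(3), Adam(tiny_generator.net.params))


# ------------------------------------------------------------- training loop

@pytest.fixture(scope="module")
def micro_rl(vocab, corpus, objectives):
    """A short but real RL run on a lightly pretrained miniature generator."""
    base = GeneratorNet(vocab, emb_dim=8, hidden_dim=16, n_layers=1,
                        max_len=60, seed=0)
    base.train_lm(corpus, epochs=15, batch_size=32, lr=5e-3, seed=0)
    agent, crossover, mutation = base.clone(), base.clone(), base.clone()
    m_hash_before = mutation.param_hash()
    cfg = ExplorerConfig(epsilon=0.05, batch_size=24, lr=1e-3,
                         plateau_patience=1, max_iterations=3, max_epochs=10,
                         eval_sample_size=50, seed=1, track_param_hashes=True)
    state = train_rl(agent, crossover, mutation, objectives,
                     scheme="pf", config=cfg)
    return dict(state=state, agent=agent, crossover=crossover,
                mutation=mutation, m_hash_before=m_hash_before)


def test_mutation_net_is_frozen(micro_rl):
    assert micro_rl["mutation"].param_hash() == micro_rl["m_hash_before"]
    hashes = {e["mutation_hash"] for e in micro_rl["state"].epoch_log}
    assert hashes == {micro_rl["m_hash_before"]}


def test_crossover_updates_only_at_iteration_boundaries(micro_rl):
    log = micro_rl["state"].epoch_log
    assert len(log) >= 2
    for prev, cur in zip(log, log[1:]):
        if cur["iteration"] != prev["iteration"]:
            # boundary: crossover becomes the agent's post-update parameters
            assert cur["crossover_hash"] == prev["agent_hash"]
        else:
            assert cur["crossover_hash"] == prev["crossover_hash"]
    assert any(cur["iteration"] != prev["iteration"]
               for prev, cur in zip(log, log[1:]))


def test_agent_parameters_change_each_epoch(micro_rl):
    hashes = [e["agent_hash"] for e in micro_rl["state"].epoch_log]
    assert len(set(hashes)) == len(hashes)


def test_history_records_the_contract_fields(micro_rl):
    for e in micro_rl["state"].epoch_log:
        for key in ("epoch", "iteration", "validity", "desirability",
                    "uniqueness", "mean_reward", "objective_j"):
            assert key in e


def test_collapsed_generator_aborts(vocab, objectives):
    gen = GeneratorNet(vocab, emb_dim=8, hidden_dim=12, n_layers=1,
                       max_len=4, seed=0)
    gen.net.params["bo"][vocab.end_index] = -50.0  # END never sampled -> all truncated
    cfg = ExplorerConfig(batch_size=8, max_epochs=10, eval_sample_size=10, seed=0)
    with pytest.raises(RLAbortError):
        train_rl(gen, gen.clone(), gen.clone(), objectives, config=cfg)


def test_explorer_config_validation():
    with pytest.raises(ValueError):
        ExplorerConfig(epsilon=1.5)
    with pytest.raises(ValueError):
        ExplorerConfig(mix="harmonic")
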