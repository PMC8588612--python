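# paretogen

De novo design of drug-like molecules by Pareto-based multi-objective
reinforcement learning over a SMILES language model.

## The problem

In polypharmacology a useful molecule rarely has to satisfy one criterion:
it should bind two related receptors but spare an anti-target such as the
hERG channel, or hit exactly one subtype of a receptor family and avoid the
others. `paretogen` is for computational chemists who want a generative
model steered by several such objectives at once, without collapsing them
into a hand-tuned weighted score up front.

## The method

A recurrent SMILES language model (embedding + stacked LSTM layers +
softmax head) is pretrained on a corpus by teacher-forced maximum
likelihood, fine-tuned on a focused set, and then optimized by REINFORCE:

    J(θ) = Σ_t log G(y_t | y_{1:t−1}) · R*(y_{1:T})

Each objective i maps a predicted potency pX_i (clipped to [3, 10]) to a
normalized score, inverted for anti-targets:

    R_i = minmax(pX_i)        high affinity required
    R_i = 1 − minmax(pX_i)    low affinity required
    R_i = 0                   SMILES invalid

A molecule is *desired* when R_i > t_i (default 0.5, i.e. pX > 6.5) on every
objective. Two schemes turn the score vector into the scalar R*:

* **WS** — dynamic weighted sum: w_i ∝ N_i^smaller / N_i^larger, so
  currently-unmet objectives get more weight, R* = Σ w_i R_i;
* **PF** — Pareto ranking: non-dominated sorting on desirability-transformed
  scores, within-front ordering by mean Tanimoto distance, and evenly
  spread rewards — undesired molecules in (0, 0.5], desired in (0.5, 1].

Exploration mixes three architecture-identical nets: the trained agent G_A,
a crossover net G_C refreshed from G_A at iteration boundaries, and a frozen
pretrained mutation net G_M consulted with probability ε per token.

The scoring environment is either trained QSAR regressors (RF / SVM / PLS /
multitask DNN on 2048-bit ECFP6 + 19 physchem descriptors) or fast
deterministic toy oracles; evaluation covers validity, desirability,
uniqueness, Solow–Polasky diversity I(A) = eᵀF⁻¹e/|A|, ring-system
substructure profiles, and SA/QED drug-likeness.

The recurrent nets, their gradients and the optimizer are implemented in
NumPy with exact manual backpropagation (finite-difference-checked in the
tests); chemistry goes through RDKit and the classic regressors through
scikit-learn.

## Worked example

`examples/05_rl_loop.py` runs the whole workflow at desk scale: pretrain a
small LSTM on a 300-molecule synthetic corpus, fine-tune, then run the
PF-scheme RL loop with three toy oracles (maximize aromatic rings and
heteroatoms, minimize rotatable bonds) at ε = 0.01. It prints:

```
fine-tuned baseline: validity 93.7%, desired 5.2%
  epoch   1 iter 0: desired 8.8% validity 91.2%
  epoch  13 iter 1: desired 17.5% validity 91.2%
  epoch  25 iter 1: desired 42.2% validity 92.2%
  epoch  37 iter 2: desired 46.8% validity 91.2%
  epoch  49 iter 3: desired 52.8% validity 91.8%
stopped: no improvement over previous iteration
after RL: validity 89.7%, desired 55.6% (was 5.2%)
```

Reading: before RL only ~5% of sampled molecules satisfy all three
objectives simultaneously; the policy gradient raises that to ~56% of 1000
samples while grammatical validity stays near 90%. The other examples each
demonstrate one capability (tokenization, generator training, the QSAR
environment, reward schemes, evaluation metrics) in under a few minutes.

A thin CLI wraps the same library surface:

```bash
paretogen fixtures --out fx --seed 7 --n 300
paretogen run --outdir run1 --corpus fx/corpus.smi \
    --objectives fx/objectives_multi_target.json --scheme pf --seed 0
```

## Layout

- `src/paretogen/` — the library: `smiles` (tokenization/vocabulary),
  `features` (descriptors), `qsar` (environment), `generator` (language
  model), `rewards` (WS/PF schemes), `explore` (RL loop), `metrics`
  (evaluation), `synthetic` (fixture generators), `pipeline` + `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, limitations.
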