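# Methods

`paretogen` implements de novo SMILES design by multi-objective reinforcement
learning: a recurrent language model proposes molecules, a set of per-target
potency predictors scores them, and a reward scheme collapses the score
vector into the scalar signal a policy gradient feeds back into the model.
This note records the model, its assumptions, the parameters that matter,
the numerical choices, and what the synthetic test bed does and does not
show about real data.

## The generative model

A molecule is a token sequence: bracket atoms (`[nH]`, `[O-]`), two-letter
halogens and `%NN` ring closures are single tokens, everything else one
character, delimited by `GO`/`END`. The language model is an embedding
(default 128) followed by stacked recurrent layers (default three LSTM
layers of 512 units; GRU available behind the `cell` switch) and a linear
softmax head over the vocabulary. Training is teacher-forced maximum
likelihood: the loss per sequence is −Σ_t log p(y_t | y_<t), averaged over
the batch and minimized with Adam (default lr 1e-3, batch 512). A held-out
validation split (default 10%) is scored every epoch and never updates
parameters; the best-validation checkpoint is retained, which is what keeps
fine-tuning from overfitting a small focused corpus.

The recurrent nets, their exact analytic gradients, and Adam are implemented
directly in NumPy (float64, CPU). The test suite checks every gradient path
against central finite differences to ~1e-7, and the stepwise sampling API
against the dense teacher-forced forward pass to 1e-12, so the training code
and the sampling code provably describe the same model.

Sampling is plain multinomial at temperature 1.0 from each step's softmax.
Sequences are cut at `END`; a sequence that reaches the length cap (default
100 tokens) without emitting `END` is counted invalid. Validity of decoded
strings is decided by the RDKit parser, and uniqueness is always computed on
canonical SMILES — raw-string uniqueness is trivially inflated by atom
reordering.

## The scoring environment

Each objective wraps a predictor returning a potency estimate pX (the
−log10 of Ki/Kd/IC50/EC50), a direction, and a threshold t (default 0.5).
Predictions are clipped to [3, 10] and min-max normalized:

    R = (pX − 3) / 7            (high affinity wanted)
    R = 1 − (pX − 3) / 7        (low affinity wanted, e.g. an anti-target)

so the conventional activity cutoff pX = 6.5 sits exactly at R = 0.5. A
*desired* molecule is valid and has R_i strictly above t_i on every
objective. Invalid SMILES score 0 everywhere.

Trained predictors operate on a 2067-D descriptor: a 2048-bit ECFP6
fingerprint (Morgan radius 3) concatenated with 19 physchem descriptors in a
fixed order (MW, logP, HBA, HBD, rotatable bonds, amide bonds, bridgehead
atoms, heteroatoms, spiro atoms, heavy atoms, fraction Csp3, aliphatic/
saturated/total/aromatic ring counts, heterocycles, valence electrons, TPSA,
Crippen MR). Features are min-max scaled with statistics from the training
split only; unseen values clip into [0, 1].

Dataset curation: duplicate (canonical molecule, target) measurements are
averaged; rows labeled inactive without a measured value are imputed at
pX 3.99 with sample weight 0.1 (measured rows weigh 1.0) — the imputed value
sits just under the pX 4 floor so negative chemical matter anchors the low
end of the regression without dominating it. Low-quality weighting is
honored by RF (default 1000 trees, squared-error splits — the regression
analogue of the classification default), the RBF-SVM (C and γ selected over
a power-of-two grid, C ∈ 2^[−5,5], γ ∈ 2^[−15,5], by inner CV) and the
multitask DNN (2048→4000→2000→1000→n_targets, ReLU, dropout 0.2, Adam
lr 1e-3, 100 epochs, with per-(molecule,task) masking so each molecule only
trains the tasks it was measured on). PLS has no sample-weight support in
scikit-learn; its fits treat all rows equally, which is documented rather
than worked around. Evaluation is out-of-fold 5-fold CV (random, seeded) or
a temporal split at a configurable cutoff year.

Toy oracles — deterministic affine maps of computable properties
(ring counts, heteroatoms, rotatable bonds, logP, …) into [3, 10] — plug
into the same `ObjectiveSpec` interface and make the whole RL loop
exercisable in seconds with no external data.

## Reward schemes

**Weighted sum (WS).** Weights are dynamic, set per batch from how hard each
objective currently is: r_i = N_i^smaller / N_i^larger (molecules below vs
above threshold on objective i), w_i = r_i / Σ r_k, R* = Σ w_i R_i. When no
molecule clears objective i the denominator is replaced by 1, which keeps
the hardest objective at the largest finite weight instead of producing an
infinity; when every molecule clears every objective the weights fall back
to uniform.

**Pareto front (PF).** Scores are first desirability-transformed
(D_i = 1 if R_i > t_i else R_i / t_i), which caps credit above threshold so
dominance comparisons concentrate on the unmet objectives. The batch is
partitioned by fast non-dominated sorting (verified against a brute-force
all-pairs oracle), fronts ordered from dominated to dominant; within a front
molecules are ordered by mean Tanimoto distance to their front peers
(most distant = most novel = better), replacing the usual crowding distance.
A global 1-based rank k is assigned along this ordering after stably moving
all undesired molecules below all desired ones (invalid molecules pinned to
the very bottom), and rewards are spread evenly:

    R* = k / (2 N_undesired)                      undesired → (0, 0.5]
    R* = 0.5 + (k − N_undesired) / (2 N_desired)  desired   → (0.5, 1]

With 1-based k the best desired molecule gets exactly 1.0 and a single
undesired molecule gets 0.5. Degenerate batches (no desired, or no
undesired) use whichever branch applies over k = 1..N. Ties in mean
Tanimoto distance keep input order (stable sort) for determinism.

## Policy gradient and exploration

The RL objective is J(θ) = Σ_t log G(y_t | y_<t) · R*(y_1:T), maximized by
Adam on its exact gradient — implemented as descent on the reward-weighted
NLL with per-sequence weights R*/B, which is algebraically the same thing
and reuses the verified likelihood gradients. A batch with all-zero rewards
therefore produces exactly zero gradient.

Exploration uses three architecture-identical nets. The mutation net G_M is
frozen at the pretrained state; the agent G_A and crossover net G_C start
from the fine-tuned model. At every token position an independent uniform
draw u decides the policy: u > ε samples from the combination of G_A and
G_C, u ≤ ε from G_M. "Combination" is the arithmetic mean of the two
per-step distributions, renormalized — symmetric and support-preserving; a
geometric-mean variant is available behind `mix="geometric"` for ablation.
With ε = 0 and G_C = G_A the mixed policy reduces exactly to plain agent
sampling (the no-exploration baseline), a property the tests pin.

An *iteration* ends when the desired fraction of molecules sampled from G_A
alone (a fixed-size evaluation sample, default 1000) has not improved for
`plateau_patience` epochs (default 3); G_C is then refreshed by copying G_A
and the next iteration starts. Training stops when an iteration's best
desired fraction fails to exceed the previous iteration's, or at the
safety caps (`max_iterations` 20, `max_epochs` 500). If five consecutive
epochs yield no valid molecule the run aborts with a diagnostic rather than
chasing gradients of nothing. All randomness — token sampling, ε draws,
batch order — flows from one seeded generator; pipeline stages derive their
seeds from the global seed via `SeedSequence([seed, stage_index])`.

## Evaluation metrics

Validity, desirability and uniqueness are the three standard coefficients
(N_valid/N_total, N_desired/N_total, N_unique/N_total, uniqueness on
canonical SMILES). Population diversity is the Solow–Polasky measure

    I(A) = eᵀ F⁻¹ e / |A|,   F_ij = exp(−θ d_ij),

on Tanimoto distances of ECFP6 fingerprints, normalized by set size into
(0, 1]. θ is not dictated by theory; the default is 1.0 and θ is reported
with every value because values are not comparable across kernels.
Duplicate molecules make F exactly singular, so a ridge of 1e-8 is added to
the diagonal and the system F x = e is solved directly instead of forming an
inverse; on distinct sets this preserves closed-form values to at least six
digits (the two-molecule closed form 2/(1 + e^{−θd}) is pinned in tests),
and a duplicated pair evaluates to ≈ 0.5 as the d→0 limit predicts.
Two all-zero fingerprints are defined to be at distance 0.

Substructure profiles report the percentage of valid molecules matching
benzene (`c1ccccc1`), furan (`c1ccoc1`) and purine ring systems; the purine
SMARTS uses plain aromatic nitrogens (`c1ncc2ncnc2n1`) so any
N-substitution or tautomer placement — caffeine, adenine — still matches.
SA (1 easy … 10 hard) and QED (0 … 1) come from the standard RDKit
implementations.

## The synthetic test bed

The fixture generator composes molecules from eight scaffolds (benzene,
pyridine, furan, pyrrole, pyrimidine, purine, cyclohexane, piperidine),
valence-safe substituent chains and terminal groups, verifying every string
with the parser, so corpora are 100% valid and deterministic per seed. The
resulting chemistry spans roughly 10–30 heavy atoms with a ~17-token
vocabulary — rich enough to make grammar learning non-trivial, small enough
to train on one CPU.

Activity tables plant an affine property signal (aromatic rings,
heteroatoms, logP) plus Gaussian noise (σ = 0.3) for three pseudo-targets,
with "Not Active" rows below pX 4.5 and ~10% duplicated measurements, so
curation, weighting and regression all get exercised with a recoverable
ground truth. The parameter-recovery dataset plants pX = 4 + 3·bit on the
fingerprint bit nearest 50% frequency (noise σ = 0.1), a signal a
random forest must find among 2067 features.

The toy objective sets mirror the two study designs: *multi-target*
(maximize aromatic-ring and heteroatom oracles, minimize the
rotatable-bond oracle) and *target-specific* (maximize heteroatoms,
minimize the other two). With thresholds at 0.5 a desired molecule needs
≥ 2 aromatic rings, ≥ 4 heteroatoms and ≤ 3 rotatable bonds — satisfiable
within the fixture chemistry but rare (~5% of a fine-tuned model's samples),
leaving clear headroom for RL.

What this test bed does **not** show: SMILES grammar at ChEMBL scale
(84-token vocabulary, stereochemistry, charges), predictor behavior on
noisy heterogeneous assay data, or reward landscapes from trained QSAR
models, whose errors correlate across similar molecules in ways toy oracles
cannot imitate. Passing here demonstrates the machinery is correct and the
optimization dynamics work; absolute percentages do not transfer to real
campaigns.

## Problem sizes used in the checks

The scaled-down RL experiment in the test suite uses a 300-molecule corpus
(seed 7), an LSTM with embedding 32, two layers of 64 units, length cap 80;
pretraining 100 epochs (batch 32, lr 5e-3), fine-tuning 15 epochs (lr 1e-3),
then PF-scheme RL with ε = 0.01, batch 96, plateau patience 4, evaluation
samples of 400, and pre/post desirability measured on 1000 samples. These
sizes were chosen once as a realistic desk-scale analogue of the full
workflow; a typical run moves the desired fraction from ~5% to ~50% while
validity stays around 90%.

## Known limitations

* The NumPy nets are exact but not fast; ChEMBL-scale pretraining (millions
  of molecules, 512-unit layers) wants a GPU framework.
* MT-DNN masking assumes missing targets are missing at random per molecule.
* The WS scheme's epsilon rule at N^larger = 0 is one reasonable choice
  among several; it affects only batches where an objective is completely
  unmet.
* Whether PF dominance should run on raw scores or desirability-transformed
  scores is a genuine design fork; this package uses the transformed scores
  (capping credit above threshold) and exposes the raw scores in
  `ScoreMatrix` for sensitivity checks.
* The diversity ridge makes I(A) well-defined on sets with duplicates but
  slightly biases values below the exact closed form (≤ 1e-6 on the sets
  tested).
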