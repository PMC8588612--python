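"""The SMILES language model: architecture wrapper, NLL training, sampling.

A :class:`GeneratorNet` couples a vocabulary with a recurrent language model
(default: embedding 128, three LSTM layers of 512 units) and provides
teacher-forced negative-log-likelihood training, autoregressive multinomial
sampling, and checkpoint persistence.  Sequences are framed as
``GO t1 .. tn`` (input) vs ``t1 .. tn END`` (target); positions past END are
masked out of the loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .nnet import Adam, RecurrentLM, log_softmax
from .smiles import Vocabulary, is_valid_smiles, tokenize

DEFAULT_MAX_LEN = 100


@dataclass
class SampleBatch:
    """Sampled sequences with their log-likelihood under the emitting model."""

    token_ids: list[np.ndarray]          # per sequence, token ids incl. trailing END
    log_likelihood: np.ndarray           # (n,) log p of each sequence
    smiles: list[str]
    valid: np.ndarray                    # (n,) bool
    canonical: list[str | None]
    truncated: np.ndarray = field(default=None)  # hit the length cap

    def __len__(self) -> int:
        return len(self.smiles)


class GeneratorNet:
    """Vocabulary + recurrent LM + sampling/training utilities."""

    def __init__(self, vocab: Vocabulary, emb_dim: int = 128, hidden_dim: int = 512,
                 n_layers: int = 3, cell: str = "lstm", max_len: int = DEFAULT_MAX_LEN,
                 seed: int = 0):
        self.vocab = vocab
        self.max_len = max_len
        self.net = RecurrentLM(len(vocab), emb_dim=emb_dim, hidden_dim=hidden_dim,
                               n_layers=n_layers, cell=cell, seed=seed)

    # ------------------------------------------------------------------ misc

    def clone(self) -> "GeneratorNet":
        other = GeneratorNet.__new__(GeneratorNet)
        other.vocab = self.vocab
        other.max_len = self.max_len
        other.net = self.net.clone()
        return other

    def param_hash(self) -> str:
        return self.net.hash()

    # ------------------------------------------------------------- encoding

    def encode_corpus(self, corpus: Iterable[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pad a tokenizable corpus into (inputs, targets, mask) arrays.

        inputs[b] = [GO, t1..tn, END...]; targets[b] = [t1..tn, END, END...];
        mask covers the n+1 real target positions (chemical tokens plus END).
        """
        encoded = []
        for smi in corpus:
            seq = tokenize(smi, self.vocab)
            encoded.append(self.vocab.encode(seq.chemical_tokens))
        if not encoded:
            raise ValueError("empty corpus")
        T = max(len(e) for e in encoded) + 1
        B = len(encoded)
        go, end = self.vocab.go_index, self.vocab.end_index
        inputs = np.full((B, T), end, dtype=np.int64)
        targets = np.full((B, T), end, dtype=np.int64)
        mask = np.zeros((B, T))
        for b, e in enumerate(encoded):
            n = len(e)
            inputs[b, 0] = go
            inputs[b, 1:n + 1] = e
            targets[b, :n] = e
            targets[b, n] = end
            mask[b, :n + 1] = 1.0
        return inputs, targets, mask

    # ----------------------------------------------------------------- loss

    def nll_loss(self, inputs: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
        """Mean per-sequence negative log-likelihood of a padded batch."""
        if inputs.max() >= len(self.vocab) or targets.max() >= len(self.vocab):
            raise ValueError("token index out of vocabulary")
        return float(self.net.sequence_nll(inputs, targets, mask).mean())

    def sequence_log_likelihood(self, smiles_or_ids: Sequence) -> np.ndarray:
        """Re-score sequences: log p of each under the current parameters."""
        ids = []
        for item in smiles_or_ids:
            if isinstance(item, str):
                seq = tokenize(item, self.vocab)
                e = self.vocab.encode(seq.chemical_tokens) + [self.vocab.end_index]
            else:
                e = list(item)
                if not e or e[-1] != self.vocab.end_index:
                    e = e + [self.vocab.end_index]
            ids.append(e)
        T = max(len(e) for e in ids)
        B = len(ids)
        go, end = self.vocab.go_index, self.vocab.end_index
        inputs = np.full((B, T), end, dtype=np.int64)
        targets = np.full((B, T), end, dtype=np.int64)
        mask = np.zeros((B, T))
        for b, e in enumerate(ids):
            inputs[b, 0] = go
            inputs[b, 1:len(e)] = e[:-1]
            targets[b, :len(e)] = e
            mask[b, :len(e)] = 1.0
        return -self.net.sequence_nll(inputs, targets, mask)

    # ------------------------------------------------------------- training

    def train_lm(self, corpus: Sequence[str], epochs: int = 50, batch_size: int = 512,
                 lr: float = 1e-3, validation_fraction: float = 0.1,
                 seed: int = 0) -> dict:
        """Teacher-forced NLL training with Adam; keeps the best-validation
        checkpoint (the validation split never updates parameters).

        Returns a history dict with per-epoch train and validation losses.
        """
        corpus = list(corpus)
        if not corpus:
            raise ValueError("empty corpus")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(corpus))
        n_val = max(1, int(round(validation_fraction * len(corpus)))) if len(corpus) > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order, order
        train = [corpus[i] for i in train_idx]
        val = [corpus[i] for i in val_idx] or train
        vin, vtg, vms = self.encode_corpus(val)
        opt = Adam(self.net.params, lr=lr)
        history = {"train_loss": [], "valid_loss": []}
        best = (np.inf, None)
        for _ in range(epochs):
            perm = rng.permutation(len(train))
            epoch_loss, n_seen = 0.0, 0
            for start in range(0, len(train), batch_size):
                batch = [train[i] for i in perm[start:start + batch_size]]
                binp, btg, bms = self.encode_corpus(batch)
                loss, grads = self.net.loss_and_grads(binp, btg, bms)
                opt.step(grads)
                epoch_loss += loss * len(batch)
                n_seen += len(batch)
            vloss = self.nll_loss(vin, vtg, vms)
            history["train_loss"].append(epoch_loss / n_seen)
            history["valid_loss"].append(vloss)
            if vloss < best[0]:
                best = (vloss, {k: v.copy() for k, v in self.net.params.items()})
        if best[1] is not None:
            self.net.params = best[1]
        return history

    # ------------------------------------------------------------- sampling

    def sample(self, n: int, rng: np.random.Generator | None = None,
               max_len: int | None = None, step_fn=None) -> SampleBatch:
        """Autoregressive multinomial sampling of ``n`` sequences.

        ``step_fn(token_ids, states) -> (probs, states)`` may replace the
        plain single-net step — the exploration strategy plugs its mixed
        three-net policy in here.  Sequences that hit the length cap are
        flagged truncated and counted invalid.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = rng if rng is not None else np.random.default_rng()
        max_len = max_len or self.max_len
        go, end = self.vocab.go_index, self.vocab.end_index
        tokens = np.full(n, go, dtype=np.int64)
        if step_fn is None:
            states = self.net.init_state(n)
            step_fn = lambda tok, st: self.net.step(tok, st)
        else:
            states = None
        finished = np.zeros(n, dtype=bool)
        loglik = np.zeros(n)
        seqs: list[list[int]] = [[] for _ in range(n)]
        for _ in range(max_len):
            probs, states = step_fn(tokens, states)
            # vectorized multinomial draw via inverse CDF
            cdf = np.cumsum(probs, axis=1)
            cdf[:, -1] = 1.0
            draws = rng.random(n)
            nxt = (draws[:, None] < cdf).argmax(axis=1)
            logp = np.log(np.maximum(probs[np.arange(n), nxt], 1e-300))
            active = ~finished
            loglik[active] += logp[active]
            for i in np.nonzero(active)[0]:
                seqs[i].append(int(nxt[i]))
            finished |= (nxt == end)
            if finished.all():
                break
            # finished sequences keep feeding END; their state no longer matters
            tokens = np.where(finished, end, nxt)
        truncated = ~finished
        smiles, valid, canonical = [], [], []
        for i, s in enumerate(seqs):
            toks = s[:-1] if (s and s[-1] == end) else s
            smi = "".join(self.vocab.tokens[t] for t in toks)
            smiles.append(smi)
            if truncated[i]:
                valid.append(False)
                canonical.append(None)
            else:
                ok, can = is_valid_smiles(smi)
                valid.append(ok)
                canonical.append(can)
        return SampleBatch(token_ids=[np.asarray(s, dtype=np.int64) for s in seqs],
                           log_likelihood=loglik, smiles=smiles,
                           valid=np.asarray(valid, dtype=bool), canonical=canonical,
                           truncated=truncated)

    def greedy_decode(self, max_len: int | None = None) -> str:
        """Most-likely token at every step; used for memorization checks."""
        max_len = max_len or self.max_len
        go, end = self.vocab.go_index, self.vocab.end_index
        tokens = np.array([go])
        states = self.net.init_state(1)
        out = []
        for _ in range(max_len):
            probs, states = self.net.step(tokens, states)
            nxt = int(probs[0].argmax())
            if nxt == end:
                break
            out.append(nxt)
            tokens = np.array([nxt])
        return "".join(self.vocab.tokens[t] for t in out)

    # ---------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.net.params)
        self.vocab.save(path / "vocab.txt")
        manifest = {**self.net.config(), "max_len": self.max_len}
        (path / "config.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorNet":
        path = Path(path)
        cfg = json.loads((path / "config.json").read_text())
        vocab = Vocabulary.load(path / "vocab.txt")
        gen = cls(vocab, emb_dim=cfg["emb_dim"], hidden_dim=cfg["hidden_dim"],
                  n_layers=cfg["n_layers"], cell=cfg["cell"], max_len=cfg["max_len"])
        with np.load(path / "params.npz") as data:
            gen.net.params = {k: data[k] for k in data.files}
        return gen
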