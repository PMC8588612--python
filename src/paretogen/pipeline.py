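"""End-to-end orchestration: pretrain → finetune → RL → sample → evaluate.

A :class:`RunConfig` captures every knob of a run and is persisted next to
the artifacts, so any run can be replayed bit-compatibly from its config and
seed.  One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` (documented, stable across
platforms); every stage's randomness flows from its own derived seed.

Stages that already left their artifacts on disk are skipped on rerun, so a
pipeline can resume after an interruption.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .explore import ExplorerConfig, train_rl
from .generator import GeneratorNet
from .metrics import evaluate
from .qsar import load_objectives
from .smiles import build_vocabulary, read_smiles_file, write_smiles_file

logger = logging.getLogger(__name__)

_STAGES = ("pretrain", "finetune", "rl", "sample", "evaluate")


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed below 2^31, derived from the run's global seed."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    outdir: str
    corpus: str                        # pretraining corpus (one SMILES/line)
    objectives: str                    # objective config JSON
    finetune_corpus: str | None = None  # defaults to `corpus`
    scheme: str = "pf"
    epsilon: float = 1e-2
    seed: int = 0
    # generator architecture
    emb_dim: int = 128
    hidden_dim: int = 512
    n_layers: int = 3
    cell: str = "lstm"
    max_len: int = 100
    # likelihood training
    pretrain_epochs: int = 50
    finetune_epochs: int = 20
    batch_size: int = 512
    lr: float = 1e-3
    # RL
    rl_batch_size: int = 64
    plateau_patience: int = 3
    max_iterations: int = 20
    max_rl_epochs: int = 500
    eval_sample_size: int = 1000
    # evaluation
    n_samples: int = 1000
    theta: float = 1.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Run (or resume) the full training pipeline; returns artifact paths
    plus the final evaluation report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    logger.info("pipeline start (config hash %s)", config.config_hash())

    corpus = read_smiles_file(config.corpus)
    ft_corpus = (read_smiles_file(config.finetune_corpus)
                 if config.finetune_corpus else corpus)
    artifacts: dict = {"config_hash": config.config_hash()}

    def _gen_kwargs():
        return dict(emb_dim=config.emb_dim, hidden_dim=config.hidden_dim,
                    n_layers=config.n_layers, cell=config.cell,
                    max_len=config.max_len)

    # -- pretrain ------------------------------------------------------------
    pre_dir = out / "pretrained"
    try:
        if (pre_dir / "config.json").exists():
            logger.info("pretrain: checkpoint found, skipping")
            pretrained = GeneratorNet.load(pre_dir)
        else:
            vocab, skipped = build_vocabulary(corpus)
            if skipped:
                logger.warning("pretrain: skipped %d unparseable SMILES", skipped)
            pretrained = GeneratorNet(vocab, seed=derive_seed(config.seed, "pretrain"),
                                      **_gen_kwargs())
            hist = pretrained.train_lm(
                corpus, epochs=config.pretrain_epochs, batch_size=config.batch_size,
                lr=config.lr, seed=derive_seed(config.seed, "pretrain"))
            pretrained.save(pre_dir)
            (pre_dir / "history.json").write_text(json.dumps(hist))
    except Exception as exc:
        raise StageError("pretrain", exc) from exc
    artifacts["pretrained"] = str(pre_dir)

    # -- finetune ------------------------------------------------------------
    ft_dir = out / "finetuned"
    try:
        if (ft_dir / "config.json").exists():
            logger.info("finetune: checkpoint found, skipping")
            finetuned = GeneratorNet.load(ft_dir)
        else:
            finetuned = pretrained.clone()
            hist = finetuned.train_lm(
                ft_corpus, epochs=config.finetune_epochs,
                batch_size=config.batch_size, lr=config.lr,
                seed=derive_seed(config.seed, "finetune"))
            finetuned.save(ft_dir)
            (ft_dir / "history.json").write_text(json.dumps(hist))
    except Exception as exc:
        raise StageError("finetune", exc) from exc
    artifacts["finetuned"] = str(ft_dir)

    # -- reinforcement learning ----------------------------------------------
    agent_dir = out / "agent"
    objectives = load_objectives(config.objectives)
    try:
        if (agent_dir / "config.json").exists():
            logger.info("rl: checkpoint found, skipping")
            agent = GeneratorNet.load(agent_dir)
        else:
            agent = finetuned.clone()
            crossover = finetuned.clone()
            mutation = pretrained.clone()
            rl_cfg = ExplorerConfig(
                epsilon=config.epsilon, batch_size=config.rl_batch_size,
                lr=config.lr, plateau_patience=config.plateau_patience,
                max_iterations=config.max_iterations,
                max_epochs=config.max_rl_epochs,
                eval_sample_size=config.eval_sample_size,
                seed=derive_seed(config.seed, "rl"))
            state = train_rl(agent, crossover, mutation, objectives,
                             scheme=config.scheme, config=rl_cfg)
            agent.save(agent_dir)
            with (out / "rl_log.jsonl").open("w") as fh:
                for entry in state.epoch_log:
                    fh.write(json.dumps(entry) + "\n")
            (out / "rl_summary.json").write_text(json.dumps(
                {"iterations": state.iteration_log,
                 "stopped_reason": state.stopped_reason}))
    except Exception as exc:
        raise StageError("rl", exc) from exc
    artifacts["agent"] = str(agent_dir)

    # -- sample --------------------------------------------------------------
    samples_path = out / "samples.smi"
    try:
        if samples_path.exists():
            logger.info("sample: artifact found, skipping")
            samples = read_smiles_file(samples_path)
        else:
            rng = np.random.default_rng(derive_seed(config.seed, "sample"))
            batch = agent.sample(config.n_samples, rng=rng)
            samples = batch.smiles
            write_smiles_file(samples_path, samples)
    except Exception as exc:
        raise StageError("sample", exc) from exc
    artifacts["samples"] = str(samples_path)

    # -- evaluate ------------------------------------------------------------
    report_path = out / "report.json"
    try:
        report = evaluate(samples, objectives, theta=config.theta,
                          seed=derive_seed(config.seed, "evaluate"))
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    artifacts["report"] = str(report_path)
    artifacts["eval_report"] = report.to_dict()
    logger.info("pipeline done: %s", report_path)
    return artifacts
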