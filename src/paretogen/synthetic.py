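"""Synthetic fixtures: SMILES corpora, activity tables, and toy objectives.

Everything the pipeline needs to run offline is generated here from a seed:

* a corpus of valid drug-like-ish SMILES enumerated compositionally from
  heteroaromatic/aliphatic scaffolds, safe substituent chains and terminal
  groups (every emitted string is verified with the chemistry parser, so the
  corpus is 100% valid by construction);
* a bioactivity table for three pseudo-targets whose pX is an affine
  function of computable molecular properties plus Gaussian noise, with
  duplicate measurements and "Not Active" rows to exercise the curation
  rules;
* toy-oracle objective sets mirroring the two study designs — the
  multi-target case (maximize affinity at two targets, minimize at one
  off-target) and the target-specific case (maximize one, minimize two);
* a planted-signal dataset (pX carried by one fingerprint bit) for QSAR
  parameter-recovery checks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .features import fingerprint
from .qsar import BioactivityRecord, ToyOracle, save_objectives
from .rewards import ObjectiveSpec
from .smiles import is_valid_smiles, write_smiles_file

SCAFFOLDS = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1ccoc1",           # furan
    "c1cc[nH]c1",        # pyrrole
    "c1cncnc1",          # pyrimidine
    "c1ncc2[nH]cnc2n1",  # purine
    "C1CCCCC1",          # cyclohexane
    "C1CCNCC1",          # piperidine
)
#: chain pieces: each starts with C and stays valence-safe under concatenation
BODY_FRAGMENTS = ("C", "CC", "CO", "CN", "C(C)", "C(=O)")
PREFIXES = ("", "F", "Cl")          # halogens only ever bond to the chain start
SUFFIXES = ("", "O", "N", "C", "CC", "C(=O)O", "C#N", "OC")


def make_corpus(n: int, seed: int) -> list[str]:
    """Generate ``n`` distinct valid SMILES (distinct as canonical molecules)."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    corpus: list[str] = []
    attempts = 0
    while len(corpus) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("fixture space exhausted; lower n")
        prefix = PREFIXES[rng.integers(len(PREFIXES))]
        k = int(rng.integers(0, 4))
        body = "".join(BODY_FRAGMENTS[rng.integers(len(BODY_FRAGMENTS))]
                       for _ in range(k))
        if prefix and not body.startswith("C") and k == 0:
            body = ""          # halogen directly on the scaffold is fine
        scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        second = ""
        if rng.random() < 0.35:
            second = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
        suffix = SUFFIXES[rng.integers(len(SUFFIXES))]
        smi = prefix + body + scaffold + second + suffix
        ok, can = is_valid_smiles(smi)
        if not ok or can in seen:
            continue
        seen.add(can)
        corpus.append(smi)
    return corpus


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------

#: ground-truth affine structure of the three pseudo-targets
_TARGET_TRUTH = {
    "T_arom": lambda m: 3.2 + 1.2 * rdMolDescriptors.CalcNumAromaticRings(m)
                        + 0.3 * rdMolDescriptors.CalcNumHeteroatoms(m),
    "T_het":  lambda m: 3.0 + 0.9 * rdMolDescriptors.CalcNumHeteroatoms(m),
    "T_lip":  lambda m: 4.5 + 0.8 * Crippen.MolLogP(m),
}


def make_activity_table(smiles: Sequence[str], seed: int,
                        noise_sd: float = 0.3,
                        inactive_below: float = 4.5,
                        duplicate_fraction: float = 0.1) -> list[dict]:
    """Rows of (smiles, target_id, pX, label, year) for three pseudo-targets.

    pX is the target's affine property function plus N(0, noise_sd), clipped
    to [3, 10].  Molecules whose true value falls below ``inactive_below``
    are emitted as unmeasured "Not Active" rows; a fraction of measured rows
    is duplicated with fresh noise to exercise measurement averaging.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        for target, truth in _TARGET_TRUTH.items():
            true_px = truth(mol)
            year = int(rng.integers(2005, 2021))
            if true_px < inactive_below:
                rows.append({"smiles": smi, "target_id": target, "pX": "",
                             "label": "Not Active", "year": year})
                continue
            px = float(np.clip(true_px + rng.normal(0, noise_sd), 3.0, 10.0))
            rows.append({"smiles": smi, "target_id": target,
                         "pX": round(px, 3), "label": "", "year": year})
            if rng.random() < duplicate_fraction:
                px2 = float(np.clip(true_px + rng.normal(0, noise_sd), 3.0, 10.0))
                rows.append({"smiles": smi, "target_id": target,
                             "pX": round(px2, 3), "label": "", "year": year})
    return rows


def write_activity_table(path: str | Path, rows: Sequence[dict]) -> None:
    header = ["smiles", "target_id", "pX", "label", "year"]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in header))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# toy objective sets
# ---------------------------------------------------------------------------

MULTI_TARGET_ENTRIES = [
    {"name": "T_arom", "direction": "high_affinity", "threshold": 0.5,
     "oracle": {"property": "aromatic_rings", "offset": 3.0, "scale": 2.0}},
    {"name": "T_het", "direction": "high_affinity", "threshold": 0.5,
     "oracle": {"property": "heteroatoms", "offset": 3.0, "scale": 1.0}},
    {"name": "T_rot", "direction": "low_affinity", "threshold": 0.5,
     "oracle": {"property": "rotatable_bonds", "offset": 3.0, "scale": 1.0}},
]

TARGET_SPECIFIC_ENTRIES = [
    {"name": "T_het", "direction": "high_affinity", "threshold": 0.5,
     "oracle": {"property": "heteroatoms", "offset": 3.0, "scale": 1.0}},
    {"name": "T_arom", "direction": "low_affinity", "threshold": 0.5,
     "oracle": {"property": "aromatic_rings", "offset": 3.0, "scale": 2.0}},
    {"name": "T_rot", "direction": "low_affinity", "threshold": 0.5,
     "oracle": {"property": "rotatable_bonds", "offset": 3.0, "scale": 1.0}},
]


def _entries_to_objectives(entries) -> list[ObjectiveSpec]:
    return [ObjectiveSpec(predictor=ToyOracle.from_spec(e["oracle"]),
                          direction=e["direction"], threshold=e["threshold"],
                          name=e["name"])
            for e in entries]


def multi_target_objectives() -> list[ObjectiveSpec]:
    """High affinity at two pseudo-targets, low at the off-target."""
    return _entries_to_objectives(MULTI_TARGET_ENTRIES)


def target_specific_objectives() -> list[ObjectiveSpec]:
    """High affinity at one pseudo-target, low at the two others."""
    return _entries_to_objectives(TARGET_SPECIFIC_ENTRIES)


# ---------------------------------------------------------------------------
# planted-signal dataset for parameter recovery
# ---------------------------------------------------------------------------

def make_planted_dataset(n: int = 500, seed: int = 0, noise_sd: float = 0.1
                         ) -> tuple[list[BioactivityRecord], int]:
    """Bioactivity records whose pX is carried by one fingerprint bit.

    pX = 4 + 3·bit + N(0, noise_sd) on the fingerprint bit whose frequency
    over the generated molecules is closest to 1/2 (so both classes are well
    populated).  Returns the records and the chosen bit index.
    """
    rng = np.random.default_rng(seed)
    corpus = make_corpus(n, seed)
    canon = [is_valid_smiles(s)[1] for s in corpus]
    fps = np.stack([fingerprint(s) for s in canon]).astype(float)
    freq = fps.mean(axis=0)
    bit = int(np.argmin(np.abs(freq - 0.5)))
    px = 4.0 + 3.0 * fps[:, bit] + rng.normal(0, noise_sd, size=n)
    records = [BioactivityRecord(smiles=c, target_id="T_bit", px=float(p),
                                 quality="measured", sample_weight=1.0)
               for c, p in zip(canon, px)]
    return records, bit


# ---------------------------------------------------------------------------
# one-call fixture writer
# ---------------------------------------------------------------------------

def generate_fixtures(outdir: str | Path, seed: int = 7, n_molecules: int = 200
                      ) -> dict:
    """Write corpus, activity table and objective configs under ``outdir``.

    Deterministic: the same seed yields byte-identical files.  Returns the
    paths of everything written.
    """
    if n_molecules < 50:
        raise ValueError("n_molecules must be at least 50")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus = make_corpus(n_molecules, seed)
    paths = {
        "corpus": outdir / "corpus.smi",
        "activity": outdir / "activity.tsv",
        "objectives_multi_target": outdir / "objectives_multi_target.json",
        "objectives_target_specific": outdir / "objectives_target_specific.json",
    }
    write_smiles_file(paths["corpus"], corpus)
    write_activity_table(paths["activity"], make_activity_table(corpus, seed + 1))
    save_objectives(paths["objectives_multi_target"], MULTI_TARGET_ENTRIES)
    save_objectives(paths["objectives_target_specific"], TARGET_SPECIFIC_ENTRIES)
    return {k: str(v) for k, v in paths.items()}
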