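"""Evaluation of generated molecule sets.

Covers the standard generator coefficients (validity, desirability,
uniqueness), Solow–Polasky population diversity on a Tanimoto-distance
kernel, ring-system substructure profiles, and SA/QED drug-likeness.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import QED

from .features import fingerprint
from .smiles import is_valid_smiles

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

#: ring-system SMARTS; the purine pattern uses plain aromatic n so any
#: N-substitution/tautomer placement (e.g. caffeine) still matches
SUBSTRUCTURE_SMARTS = {
    "benzene": "c1ccccc1",
    "furan": "c1ccoc1",
    "purine": "c1ncc2ncnc2n1",
}
_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in SUBSTRUCTURE_SMARTS.items()}


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """1 − |a ∩ b| / |a ∪ b| on binary fingerprints; two empty sets are at 0."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return 1.0 - (a & b).sum() / union


def coefficients(smiles: Sequence[str], objectives=None) -> dict:
    """Validity, desirability and uniqueness of a generated set (fractions).

    validity = N_valid/N_total; uniqueness = N_unique/N_total on canonical
    SMILES of the valid molecules; desirability = N_desired/N_total with the
    desired flag from the all-objectives-above-threshold rule (0 when no
    objectives are given).
    """
    smiles = list(smiles)
    if not smiles:
        raise ValueError("empty molecule list")
    n = len(smiles)
    canon = []
    for smi in smiles:
        ok, can = is_valid_smiles(smi)
        if ok:
            canon.append(can)
    validity = len(canon) / n
    uniqueness = len(set(canon)) / n
    desirability_frac = 0.0
    if objectives:
        from .rewards import score_batch  # local import avoids a module cycle
        matrix = score_batch(smiles, objectives)
        desirability_frac = float(matrix.desired.sum()) / n
    return {"validity": validity, "desirability": desirability_frac,
            "uniqueness": uniqueness}


def solow_polasky_diversity(smiles: Sequence[str], theta: float = 1.0,
                            ridge: float = 1e-8) -> float:
    """I(A) = eᵀ F⁻¹ e / |A| with kernel f(d) = exp(−θ d) on Tanimoto distances.

    All molecules must be valid.  Duplicates make F singular, so a ridge
    (default 1e-8) is added to the diagonal and the linear system is solved
    directly instead of forming an explicit inverse; on distinct sets this
    preserves the closed-form value to at least six digits.
    """
    smiles = list(smiles)
    if not smiles:
        raise ValueError("empty molecule set")
    bad = [s for s in smiles if not is_valid_smiles(s)[0]]
    if bad:
        raise ValueError(f"invalid molecules in diversity input: {bad}")
    m = len(smiles)
    if m == 1:
        return 1.0
    fps = [fingerprint(s) for s in smiles]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = tanimoto_distance(fps[i], fps[j])
    F = np.exp(-theta * D) + ridge * np.eye(m)
    x = np.linalg.solve(F, np.ones(m))
    return float(x.sum() / m)


def substructure_profile(smiles: Sequence[str]) -> dict:
    """Fraction of *valid* molecules containing each ring system, as %."""
    smiles = list(smiles)
    if not smiles:
        raise ValueError("empty molecule list")
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    mols = [m for m in mols if m is not None and m.GetNumAtoms() > 0]
    out = {}
    for name, patt in _PATTERNS.items():
        if not mols:
            out[name] = 0.0
            continue
        hits = sum(1 for m in mols if m.HasSubstructMatch(patt))
        out[name] = 100.0 * hits / len(mols)
    return out


def drug_likeness(smiles: Sequence[str]) -> dict:
    """Per-molecule SA (1 easy … 10 hard) and QED (0 … 1 drug-like) scores.

    Invalid molecules are skipped; their count is reported.
    """
    sa, qed, skipped = [], [], 0
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:   # "" parses as an empty mol
            skipped += 1
            continue
        sa.append(sascorer.calculateScore(mol))
        qed.append(QED.qed(mol))
    def _summary(vals):
        if not vals:
            return {"mean": float("nan"), "median": float("nan"),
                    "min": float("nan"), "max": float("nan")}
        a = np.asarray(vals)
        return {"mean": float(a.mean()), "median": float(np.median(a)),
                "min": float(a.min()), "max": float(a.max())}
    return {"sa": sa, "qed": qed, "skipped": skipped,
            "sa_summary": _summary(sa), "qed_summary": _summary(qed)}


@dataclass
class EvalReport:
    """Summary of one generated molecule set."""

    n_molecules: int
    validity_pct: float
    desirability_pct: float
    uniqueness_pct: float
    diversity: float
    diversity_theta: float
    substructures_pct: dict
    sa_summary: dict
    qed_summary: dict

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(smiles: Sequence[str], objectives=None, theta: float = 1.0,
             diversity_max: int = 1000, seed: int = 0) -> EvalReport:
    """Full evaluation of a generated set.

    Diversity is computed on the distinct valid molecules (subsampled to
    ``diversity_max`` for tractability of the m×m kernel solve; θ is reported
    alongside the value since I(A) is not comparable across θ).
    """
    smiles = list(smiles)
    coeff = coefficients(smiles, objectives)
    valid_unique = sorted({is_valid_smiles(s)[1] for s in smiles
                           if is_valid_smiles(s)[0]})
    if len(valid_unique) > diversity_max:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(valid_unique), size=diversity_max, replace=False)
        valid_unique = [valid_unique[i] for i in sorted(idx)]
    diversity = solow_polasky_diversity(valid_unique, theta=theta) if valid_unique else 0.0
    subs = substructure_profile(smiles) if valid_unique else {k: 0.0 for k in _PATTERNS}
    dl = drug_likeness(smiles)
    return EvalReport(
        n_molecules=len(smiles),
        validity_pct=100.0 * coeff["validity"],
        desirability_pct=100.0 * coeff["desirability"],
        uniqueness_pct=100.0 * coeff["uniqueness"],
        diversity=diversity,
        diversity_theta=theta,
        substructures_pct=subs,
        sa_summary=dl["sa_summary"],
        qed_summary=dl["qed_summary"],
    )
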