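"""Molecular featurization: 2048-bit ECFP6 fingerprint + 19 physchem descriptors.

Every molecule maps to a fixed 2067-dimensional vector: a radius-3 Morgan
(ECFP6) fingerprint hashed to 2048 bits followed by 19 physico-chemical
descriptors in a fixed order (see :data:`PHYSCHEM_NAMES`).
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

N_BITS = 2048
FP_RADIUS = 3  # three-bond radius -> ECFP6
N_PHYSCHEM = 19
N_FEATURES = N_BITS + N_PHYSCHEM

#: physchem block, in order
PHYSCHEM_NAMES = (
    "mol_weight",
    "logp",
    "hba",
    "hbd",
    "rotatable_bonds",
    "amide_bonds",
    "bridgehead_atoms",
    "heteroatoms",
    "spiro_atoms",
    "heavy_atoms",
    "fraction_csp3",
    "aliphatic_rings",
    "saturated_rings",
    "total_rings",
    "aromatic_rings",
    "heterocycles",
    "valence_electrons",
    "tpsa",
    "crippen_mr",
)

_morgan = GetMorganGenerator(radius=FP_RADIUS, fpSize=N_BITS)


class FeaturizationError(ValueError):
    pass


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"cannot featurize invalid SMILES {smiles!r}")
    return mol


def fingerprint(smiles: str) -> np.ndarray:
    """ECFP6 fingerprint as a dense uint8 {0,1} array of length 2048."""
    fp = _morgan.GetFingerprint(_mol(smiles))
    arr = np.zeros(N_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def physchem(smiles: str) -> np.ndarray:
    mol = _mol(smiles)
    vals = (
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcNumAmideBonds(mol),
        rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        rdMolDescriptors.CalcNumHeteroatoms(mol),
        rdMolDescriptors.CalcNumSpiroAtoms(mol),
        mol.GetNumHeavyAtoms(),
        rdMolDescriptors.CalcFractionCSP3(mol),
        rdMolDescriptors.CalcNumAliphaticRings(mol),
        rdMolDescriptors.CalcNumSaturatedRings(mol),
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        rdMolDescriptors.CalcNumHeterocycles(mol),
        Descriptors.NumValenceElectrons(mol),
        rdMolDescriptors.CalcTPSA(mol),
        Crippen.MolMR(mol),
    )
    return np.asarray(vals, dtype=np.float64)


def featurize(smiles: str) -> np.ndarray:
    """2067-D descriptor vector: [2048 fingerprint bits | 19 physchem]."""
    return np.concatenate([fingerprint(smiles).astype(np.float64), physchem(smiles)])


def featurize_many(smiles_list) -> np.ndarray:
    """Stack featurize() over a list; raises on the first invalid SMILES."""
    return np.stack([featurize(s) for s in smiles_list])
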