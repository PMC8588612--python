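"""Bioactivity dataset preparation and the QSAR scoring environment.

The "environment" that rewards the generator is a set of per-target pX
predictors: either regressors trained on bioactivity tables (RF / SVM / PLS /
multitask DNN on 2067-D descriptors) or fast deterministic toy oracles that
map computable molecular properties affinely into the pX range [3, 10].

Dataset preparation follows the standard curation rules: duplicate
(molecule, target) measurements are averaged; rows labeled inactive without a
measured value are imputed at pX 3.99 with sample weight 0.1 (measured rows
weigh 1.0), which keeps negative chemical matter in the model without letting
low-quality points dominate.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .features import featurize_many
from .nnet import MultiTaskMLP
from .rewards import PX_MAX, PX_MIN, ObjectiveSpec
from .smiles import canonicalize

LOW_QUALITY_PX = 3.99
LOW_QUALITY_WEIGHT = 0.1
ACTIVITY_THRESHOLD_PX = 6.5

#: labels (lower-cased) that mark a compound inactive without a measured pX
_INACTIVE_LABELS = {"not active", "inactive", "not_active"}

ALGORITHMS = ("RF", "SVM", "PLS", "MT-DNN", "toy_oracle")


@dataclass
class BioactivityRecord:
    smiles: str                      # canonical
    target_id: str
    px: float
    quality: str                     # "measured" | "low_quality"
    sample_weight: float
    year: int | None = None

    def __post_init__(self):
        if self.quality == "low_quality":
            assert self.px == LOW_QUALITY_PX and self.sample_weight == LOW_QUALITY_WEIGHT
        elif self.quality == "measured":
            assert self.sample_weight == 1.0


def prepare_dataset(table: pd.DataFrame | Sequence[dict]
                    ) -> tuple[list[BioactivityRecord], int]:
    """Curate a raw activity table into one record per (molecule, target).

    Rows need ``smiles``, ``target_id`` and either a numeric ``pX`` or an
    inactive ``label``; anything else is rejected (count returned).  Multiple
    measurements of the same canonical molecule/target pair are averaged; a
    pair only seen as "Not Active" is imputed at pX 3.99 with weight 0.1.
    """
    df = pd.DataFrame(table)
    required = {"smiles", "target_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table needs columns {sorted(required)}")
    rejected = 0
    groups: dict[tuple[str, str], dict] = {}
    for _, row in df.iterrows():
        can = canonicalize(str(row["smiles"]))
        if can is None:
            rejected += 1
            continue
        px = row.get("pX", None)
        if px is None or px == "" or (isinstance(px, float) and np.isnan(px)):
            px = None
        else:
            px = float(px)
        label = str(row.get("label", "") or "").strip().lower()
        year = row.get("year", None)
        year = None if year is None or (isinstance(year, float) and np.isnan(year)) else int(year)
        if px is None and label not in _INACTIVE_LABELS:
            rejected += 1
            continue
        key = (can, str(row["target_id"]))
        g = groups.setdefault(key, {"px": [], "years": []})
        if px is not None:
            g["px"].append(px)
        if year is not None:
            g["years"].append(year)
    records = []
    for (can, target), g in groups.items():
        year = min(g["years"]) if g["years"] else None
        if g["px"]:
            records.append(BioactivityRecord(
                smiles=can, target_id=target, px=float(np.mean(g["px"])),
                quality="measured", sample_weight=1.0, year=year))
        else:
            records.append(BioactivityRecord(
                smiles=can, target_id=target, px=LOW_QUALITY_PX,
                quality="low_quality", sample_weight=LOW_QUALITY_WEIGHT, year=year))
    return records, rejected


def read_activity_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# toy oracles
# ---------------------------------------------------------------------------

def _prop_heteroatom_fraction(mol):
    heavy = mol.GetNumHeavyAtoms()
    return rdMolDescriptors.CalcNumHeteroatoms(mol) / heavy if heavy else 0.0

#: deterministic molecular properties available to toy oracles
ORACLE_PROPERTIES = {
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "total_rings": rdMolDescriptors.CalcNumRings,
    "heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
    "hbd": rdMolDescriptors.CalcNumHBD,
    "hba": rdMolDescriptors.CalcNumHBA,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "logp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "mol_weight": Descriptors.MolWt,
    "heteroatom_fraction": _prop_heteroatom_fraction,
}


class ToyOracle:
    """Deterministic stand-in predictor: pX = clip(offset + scale·prop, 3, 10)."""

    def __init__(self, property_name: str, offset: float = 3.0, scale: float = 1.0):
        if property_name not in ORACLE_PROPERTIES:
            raise ValueError(f"unknown property {property_name!r}; "
                             f"choose from {sorted(ORACLE_PROPERTIES)}")
        self.property_name = property_name
        self.offset = float(offset)
        self.scale = float(scale)
        self._fn = ORACLE_PROPERTIES[property_name]

    def __call__(self, smiles: Sequence[str]) -> np.ndarray:
        out = np.empty(len(smiles))
        for i, smi in enumerate(smiles):
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"toy oracle got invalid SMILES {smi!r}")
            out[i] = self.offset + self.scale * self._fn(mol)
        return np.clip(out, PX_MIN, PX_MAX)

    def spec(self) -> dict:
        return {"property": self.property_name, "offset": self.offset,
                "scale": self.scale}

    @classmethod
    def from_spec(cls, spec: dict) -> "ToyOracle":
        return cls(spec["property"], spec.get("offset", 3.0), spec.get("scale", 1.0))


def toy_oracle(spec: dict | str) -> "Predictor":
    """Build a toy-oracle Predictor from a spec dict (training is a no-op)."""
    if isinstance(spec, str):
        spec = json.loads(spec)
    oracle = ToyOracle.from_spec(spec)
    return Predictor(algorithm="toy_oracle", target_id=spec.get("target", ""),
                     model=oracle, scaler=None)


# ---------------------------------------------------------------------------
# trained predictors
# ---------------------------------------------------------------------------

_SVM_DEFAULT_GRID = {
    "C": [2.0 ** p for p in range(-5, 6)],
    "gamma": [2.0 ** p for p in range(-15, 6)],
}


@dataclass
class Predictor:
    """A fitted pX regressor (or toy oracle) for one target.

    ``predict`` always returns pX estimates clipped to [3, 10] — the range
    the reward normalization assumes — even when the underlying regressor
    extrapolates beyond it.
    """

    algorithm: str
    target_id: str
    model: object
    scaler: MinMaxScaler | None
    hyperparams: dict | None = None
    targets: tuple[str, ...] | None = None   # MT-DNN task order
    training_hash: str | None = None

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        if self.algorithm == "toy_oracle":
            return self.model(smiles)
        X = featurize_many(smiles)
        X = self.scaler.transform(X)
        y = np.asarray(self.model.predict(X))
        if y.ndim == 2:
            col = self.targets.index(self.target_id) if self.targets else 0
            y = y[:, col]
        return np.clip(y.ravel(), PX_MIN, PX_MAX)

    def __call__(self, smiles: Sequence[str]) -> np.ndarray:
        return self.predict(smiles)

    def for_target(self, target_id: str) -> "Predictor":
        """Bind a multitask model to one of its output targets."""
        if self.targets and target_id not in self.targets:
            raise ValueError(f"model was not trained on target {target_id!r}")
        return Predictor(algorithm=self.algorithm, target_id=target_id,
                         model=self.model, scaler=self.scaler,
                         hyperparams=self.hyperparams, targets=self.targets,
                         training_hash=self.training_hash)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"algorithm": self.algorithm, "target_id": self.target_id,
                    "hyperparams": self.hyperparams, "targets": self.targets,
                    "training_hash": self.training_hash}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if self.algorithm == "toy_oracle":
            (path / "oracle.json").write_text(json.dumps(self.model.spec()))
        else:
            joblib.dump({"model": self.model, "scaler": self.scaler},
                        path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        targets = manifest.get("targets")
        if manifest["algorithm"] == "toy_oracle":
            oracle = ToyOracle.from_spec(json.loads((path / "oracle.json").read_text()))
            model, scaler = oracle, None
        else:
            blob = joblib.load(path / "model.joblib")
            model, scaler = blob["model"], blob["scaler"]
        return cls(algorithm=manifest["algorithm"], target_id=manifest["target_id"],
                   model=model, scaler=scaler, hyperparams=manifest.get("hyperparams"),
                   targets=tuple(targets) if targets else None,
                   training_hash=manifest.get("training_hash"))


def _dataset_hash(records: Sequence[BioactivityRecord]) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: (r.smiles, r.target_id)):
        h.update(f"{r.smiles}\t{r.target_id}\t{r.px:.6f}\t{r.sample_weight}".encode())
    return h.hexdigest()


def train_predictor(records: Sequence[BioactivityRecord], algorithm: str,
                    target: str | None = None, hyperparams: dict | None = None,
                    seed: int = 0) -> Predictor:
    """Fit a QSAR regressor on prepared records.

    Features are min-max scaled with statistics from the training data only
    (unseen values clip into [0, 1]).  RF defaults to 1000 trees; the SVM
    selects C/γ over a power-of-two grid by inner CV; the MT-DNN trains one
    output per target with a masked, weighted MSE.  Sample weights are
    honored by RF, SVM and MT-DNN (PLS has no weighting support).
    """
    hp = dict(hyperparams or {})
    if algorithm == "toy_oracle":
        return toy_oracle(hp["oracle"] if "oracle" in hp else hp)
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    records = list(records)
    targets = sorted({r.target_id for r in records})
    if target is None:
        if algorithm != "MT-DNN" and len(targets) > 1:
            raise ValueError("multiple targets present; specify which to train")
        target = targets[0]
    if algorithm == "MT-DNN":
        subset = records
    else:
        subset = [r for r in records if r.target_id == target]
    if len({r.smiles for r in subset}) < 2:
        raise ValueError("need at least two distinct molecules to train")

    if algorithm == "MT-DNN":
        mols = sorted({r.smiles for r in subset})
        mol_idx = {s: i for i, s in enumerate(mols)}
        Y = np.full((len(mols), len(targets)), np.nan)
        W = np.zeros((len(mols), len(targets)))
        for r in subset:
            i, j = mol_idx[r.smiles], targets.index(r.target_id)
            Y[i, j] = r.px
            W[i, j] = r.sample_weight
        X = featurize_many(mols)
        scaler = MinMaxScaler(clip=True).fit(X)
        Xs = scaler.transform(X)
        net = MultiTaskMLP(
            n_features=Xs.shape[1], n_tasks=len(targets),
            hidden=hp.get("hidden", (4000, 2000, 1000)),
            dropout=hp.get("dropout", 0.2), lr=hp.get("lr", 1e-3),
            epochs=hp.get("epochs", 100), batch_size=hp.get("batch_size", 256),
            seed=seed)
        net.fit(Xs, Y, sample_weight=W)
        return Predictor(algorithm=algorithm, target_id=target, model=net,
                         scaler=scaler, hyperparams=hp, targets=tuple(targets),
                         training_hash=_dataset_hash(subset))

    mols = [r.smiles for r in subset]
    y = np.array([r.px for r in subset])
    w = np.array([r.sample_weight for r in subset])
    if np.ptp(y) == 0:
        warnings.warn("constant target values; model will be degenerate",
                      UserWarning, stacklevel=2)
    X = featurize_many(mols)
    scaler = MinMaxScaler(clip=True).fit(X)
    Xs = scaler.transform(X)
    if algorithm == "RF":
        model = RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 1000),
            max_features=hp.get("max_features", 1.0),
            random_state=seed, n_jobs=1)
        model.fit(Xs, y, sample_weight=w)
    elif algorithm == "SVM":
        grid = {"C": hp.get("C_grid", _SVM_DEFAULT_GRID["C"]),
                "gamma": hp.get("gamma_grid", _SVM_DEFAULT_GRID["gamma"])}
        inner = KFold(n_splits=hp.get("inner_folds", 3), shuffle=True,
                      random_state=seed)
        search = GridSearchCV(SVR(kernel="rbf"), grid, cv=inner,
                              scoring="neg_mean_squared_error", n_jobs=1)
        search.fit(Xs, y)
        model = SVR(kernel="rbf", **search.best_params_)
        model.fit(Xs, y, sample_weight=w)
    elif algorithm == "PLS":
        n_comp = min(hp.get("n_components", 10), Xs.shape[0] - 1, Xs.shape[1])
        model = PLSRegression(n_components=max(1, n_comp))
        model.fit(Xs, y)  # PLS has no sample_weight support
    else:  # pragma: no cover
        raise AssertionError(algorithm)
    return Predictor(algorithm=algorithm, target_id=target, model=model,
                     scaler=scaler, hyperparams=hp,
                     training_hash=_dataset_hash(subset))


def load_objectives(path: str | Path) -> list[ObjectiveSpec]:
    """Read an objective config: a JSON list of per-objective entries.

    Each entry has ``direction`` (high_affinity / low_affinity), optional
    ``threshold`` (default 0.5) and ``name``, and either an inline toy
    ``oracle`` spec or a ``predictor_path`` pointing at a saved model.
    """
    entries = json.loads(Path(path).read_text())
    objectives = []
    for e in entries:
        if "oracle" in e:
            pred = toy_oracle(e["oracle"])
        elif "predictor_path" in e:
            pred = Predictor.load(e["predictor_path"])
        else:
            raise ValueError("objective entry needs 'oracle' or 'predictor_path'")
        objectives.append(ObjectiveSpec(
            predictor=pred, direction=e["direction"],
            threshold=e.get("threshold", 0.5), name=e.get("name", "")))
    return objectives


def save_objectives(path: str | Path, entries: list[dict]) -> None:
    Path(path).write_text(json.dumps(entries, indent=2))


def evaluate_predictor(predictor: Predictor, records: Sequence[BioactivityRecord],
                       scheme: str = "cv5", cutoff_year: int = 2015,
                       seed: int = 0) -> dict:
    """Out-of-sample R² and RMSE by 5-fold CV or a temporal split.

    Folds refit the predictor's algorithm/hyperparameters from scratch on the
    training portion; cv5 reports out-of-fold metrics over all records of the
    predictor's target, the temporal scheme trains on records measured before
    ``cutoff_year`` and tests on the rest (every record then needs a year).
    """
    subset = [r for r in records if r.target_id == predictor.target_id] or list(records)
    if predictor.algorithm == "toy_oracle":
        y = np.array([r.px for r in subset])
        pred = predictor.predict([r.smiles for r in subset])
        return {"R2": float(r2_score(y, pred)),
                "RMSE": float(np.sqrt(mean_squared_error(y, pred)))}
    if scheme == "cv5":
        kf = KFold(n_splits=5, shuffle=True, random_state=seed)
        y_true = np.array([r.px for r in subset])
        y_pred = np.empty(len(subset))
        idx = np.arange(len(subset))
        for train_i, test_i in kf.split(idx):
            fold = train_predictor([subset[i] for i in train_i], predictor.algorithm,
                                   target=predictor.target_id,
                                   hyperparams=predictor.hyperparams, seed=seed)
            y_pred[test_i] = fold.predict([subset[i].smiles for i in test_i])
    elif scheme == "temporal":
        if any(r.year is None for r in subset):
            raise ValueError("temporal split requires a year on every record")
        train = [r for r in subset if r.year < cutoff_year]
        test = [r for r in subset if r.year >= cutoff_year]
        if not train or not test:
            raise ValueError(f"temporal split at {cutoff_year} puts all records "
                             "on one side")
        fold = train_predictor(train, predictor.algorithm,
                               target=predictor.target_id,
                               hyperparams=predictor.hyperparams, seed=seed)
        y_true = np.array([r.px for r in test])
        y_pred = fold.predict([r.smiles for r in test])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return {"R2": float(r2_score(y_true, y_pred)),
            "RMSE": float(np.sqrt(mean_squared_error(y_true, y_pred)))}
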