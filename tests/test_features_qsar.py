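import numpy as np
import pandas as pd
import pytest

from paretogen import (BioactivityRecord, ToyOracle, evaluate_predictor,
                       featurize, fingerprint, make_planted_dataset,
                       prepare_dataset, toy_oracle, train_predictor)
from paretogen.features import N_BITS, N_FEATURES, PHYSCHEM_NAMES, FeaturizationError
from paretogen.qsar import LOW_QUALITY_PX, LOW_QUALITY_WEIGHT


# -------------------------------------------------------------- featurizer

@pytest.mark.parametrize("smiles", ["c1ccccc1", "CCO", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"])
def test_featurize_length_is_2067(smiles):
    vec = featurize(smiles)
    assert vec.shape == (N_FEATURES,) == (2067,)
    assert len(PHYSCHEM_NAMES) == 19
    assert np.isfinite(vec).all()


def test_methane_heavy_atom_count_is_one():
    vec = featurize("C")
    heavy_idx = N_BITS + PHYSCHEM_NAMES.index("heavy_atoms")
    assert vec[heavy_idx] == 1


def test_fingerprint_nonempty_for_ethanol():
    assert fingerprint("CCO").sum() >= 1


def test_featurize_invariant_to_atom_ordering():
    assert featurize("OCC") == pytest.approx(featurize("CCO"))


def test_featurize_rejects_invalid_smiles():
    with pytest.raises(FeaturizationError):
        featurize("C(")


# -------------------------------------------------------- dataset curation

def test_prepare_dataset_averages_duplicates_and_imputes_inactives():
    table = pd.DataFrame([
        {"smiles": "CCO", "target_id": "T1", "pX": 6.0},
        {"smiles": "OCC", "target_id": "T1", "pX": 7.0},   # same molecule
        {"smiles": "CCN", "target_id": "T1", "pX": None, "label": "Not Active"},
        {"smiles": "CCC", "target_id": "T1", "pX": None},  # neither -> rejected
        {"smiles": "C(", "target_id": "T1", "pX": 5.0},    # invalid -> rejected
    ])
    records, rejected = prepare_dataset(table)
    assert rejected == 2
    by_smiles = {r.smiles: r for r in records}
    assert by_smiles["CCO"].px == pytest.approx(6.5)
    assert by_smiles["CCO"].sample_weight == 1.0
    inactive = by_smiles["CCN"]
    assert inactive.px == LOW_QUALITY_PX == 3.99
    assert inactive.sample_weight == LOW_QUALITY_WEIGHT == 0.1
    assert inactive.quality == "low_quality"


def test_prepare_dataset_one_record_per_molecule_target_pair():
    rows = [{"smiles": "CCO", "target_id": t, "pX": 5.0} for t in ("A", "B")]
    rows += [{"smiles": "CCO", "target_id": "A", "pX": 6.0}]
    records, _ = prepare_dataset(rows)
    keys = [(r.smiles, r.target_id) for r in records]
    assert len(keys) == len(set(keys)) == 2


# --------------------------------------------------------------- toy oracle

def test_toy_oracle_aromatic_ring_count():
    oracle = ToyOracle("aromatic_rings", offset=3.0, scale=1.0)
    assert oracle(["c1ccccc1"])[0] == pytest.approx(4.0)   # one ring
    assert oracle(["CCO"])[0] == pytest.approx(3.0)        # zero rings
    assert oracle(["c1ccccc1"] * 2) == pytest.approx(oracle(["c1ccccc1"] * 2))


def test_toy_oracle_training_is_a_noop():
    pred = train_predictor([], "toy_oracle",
                           hyperparams={"oracle": {"property": "heteroatoms"}})
    assert pred.algorithm == "toy_oracle"
    assert pred.predict(["CCO"])[0] == pytest.approx(4.0)


def test_toy_oracle_output_clipped_to_px_range():
    oracle = ToyOracle("heavy_atoms", offset=3.0, scale=5.0)
    assert oracle(["CCCCCCCCCC"])[0] == 10.0


# ----------------------------------------------------------- trained models

@pytest.fixture(scope="module")
def planted():
    records, bit = make_planted_dataset(n=150, seed=5, noise_sd=0.1)
    return records, bit


def test_train_predictor_requires_two_molecules():
    rec = BioactivityRecord("CCO", "T", 5.0, "measured", 1.0)
    with pytest.raises(ValueError):
        train_predictor([rec, rec], "RF")


def test_rf_beats_constant_baseline_on_planted_signal(planted):
    records, _ = planted
    train, test = records[:110], records[110:]
    model = train_predictor(train, "RF", hyperparams={"n_estimators": 100}, seed=0)
    y = np.array([r.px for r in test])
    pred = model.predict([r.smiles for r in test])
    rmse = np.sqrt(((pred - y) ** 2).mean())
    baseline = y.std()
    assert rmse < 0.5 * baseline


@pytest.mark.parametrize("algorithm,hp", [
    ("PLS", {"n_components": 5}),
    ("SVM", {"C_grid": [1.0, 10.0], "gamma_grid": [1e-3, 1e-2], "inner_folds": 2}),
])
def test_other_algorithms_train_and_predict(planted, algorithm, hp):
    records, _ = planted
    model = train_predictor(records[:80], algorithm, hyperparams=hp, seed=0)
    pred = model.predict([r.smiles for r in records[80:90]])
    assert pred.shape == (10,)
    assert ((pred >= 3.0) & (pred <= 10.0)).all()


def test_mtdnn_trains_multitask_with_masked_targets(planted):
    records, _ = planted
    extra = [BioactivityRecord(r.smiles, "T2", min(10.0, r.px + 1.0),
                               "measured", 1.0) for r in records[:40]]
    model = train_predictor(records[:80] + extra, "MT-DNN",
                            hyperparams={"hidden": (32,), "epochs": 30},
                            target="T_bit", seed=0)
    assert model.targets == ("T2", "T_bit")
    pred = model.predict([r.smiles for r in records[80:85]])
    assert np.isfinite(pred).all()
    pred2 = model.for_target("T2").predict([records[0].smiles])
    assert np.isfinite(pred2).all()


def test_constant_target_warns(planted):
    records, _ = planted
    const = [BioactivityRecord(r.smiles, "T", 5.0, "measured", 1.0)
             for r in records[:10]]
    with pytest.warns(UserWarning):
        train_predictor(const, "RF", hyperparams={"n_estimators": 5})


# ----------------------------------------------------------- evaluation

def test_perfect_oracle_has_zero_rmse():
    oracle_pred = toy_oracle({"property": "heteroatoms"})
    smiles = ["CCO", "CCN", "c1ccncc1", "CCOC"]
    records = [BioactivityRecord(s, "", float(oracle_pred.predict([s])[0]),
                                 "measured", 1.0) for s in smiles]
    out = evaluate_predictor(oracle_pred, records)
    assert out["RMSE"] == pytest.approx(0.0, abs=1e-12)
    assert out["R2"] == pytest.approx(1.0)


def test_constant_predictor_has_nonpositive_r2(planted):
    records, _ = planted
    const = toy_oracle({"property": "heavy_atoms", "scale": 0.0, "offset": 5.0})
    out = evaluate_predictor(const, records[:30])
    assert out["R2"] <= 0.0


def test_cv5_is_stable_across_seeds(planted):
    records, _ = planted
    subset = records[:80]
    model = train_predictor(subset, "RF", hyperparams={"n_estimators": 50}, seed=0)
    r2 = [evaluate_predictor(model, subset, scheme="cv5", seed=s)["R2"]
          for s in (0, 1)]
    assert abs(r2[0] - r2[1]) < 0.1


def test_temporal_split_requires_both_sides(planted):
    records, _ = planted
    dated = [BioactivityRecord(r.smiles, r.target_id, r.px, r.quality,
                               r.sample_weight, year=2010) for r in records[:20]]
    model = train_predictor(dated, "RF", hyperparams={"n_estimators": 5}, seed=0)
    with pytest.raises(ValueError):
        evaluate_predictor(model, dated, scheme="temporal", cutoff_year=2015)


def test_temporal_split_evaluates(planted):
    records, _ = planted
    rng = np.random.default_rng(0)
    dated = [BioactivityRecord(r.smiles, r.target_id, r.px, r.quality,
                               r.sample_weight, year=int(rng.integers(2010, 2020)))
             for r in records[:100]]
    model = train_predictor(dated, "RF", hyperparams={"n_estimators": 50}, seed=0)
    out = evaluate_predictor(model, dated, scheme="temporal", cutoff_year=2015)
    assert np.isfinite(out["R2"]) and out["RMSE"] >= 0


def test_predictor_save_load_round_trip(tmp_path, planted):
    records, _ = planted
    model = train_predictor(records[:40], "RF", hyperparams={"n_estimators": 10},
                            seed=0)
    model.save(tmp_path / "rf")
    from paretogen import Predictor
    loaded = Predictor.load(tmp_path / "rf")
    probe = [r.smiles for r in records[40:45]]
    assert loaded.predict(probe) == pytest.approx(model.predict(probe))
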