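import numpy as np
import pandas as pd
import pytest

from rtbridge.errors import (DegenerateFitError, InsufficientAnchorsError,
                             InsufficientDataError)
from rtbridge.prediction import (DescriptorMatrix, FAST_GRID,
                                 clean_descriptor_matrix,
                                 compute_descriptors, predict_and_calibrate,
                                 train_local_model, train_rt_model)
from rtbridge.simulate import (SimulationConfig, simulate_compounds,
                               simulate_descriptors)


# ---------------------------------------------------------------- descriptors
def test_compute_descriptors_well_formed_molecule():
    dm = compute_descriptors(["CCO"], ids=["ethanol"], include_3d=False)
    row = dm.values.loc["ethanol"]
    assert row.notna().mean() > 0.9
    assert dm.cleaning_log["failed_parse"] == []


def test_compute_descriptors_flags_unparseable():
    dm = compute_descriptors(["CCO", "not_a_smiles"], ids=["a", "b"],
                             include_3d=False)
    assert dm.cleaning_log["failed_parse"] == ["b"]
    assert dm.values.loc["b"].isna().all()


def test_compute_descriptors_canonicalization_invariant():
    # same molecule written two ways -> identical descriptor rows
    dm = compute_descriptors(["OCC", "CCO"], ids=["a", "b"],
                             include_3d=False)
    assert np.allclose(dm.values.loc["a"], dm.values.loc["b"],
                       equal_nan=True)


# ------------------------------------------------------------------- cleaning
def _raw_matrix():
    rng = np.random.default_rng(0)
    n = 40
    base = rng.normal(size=(n, 6))
    frame = pd.DataFrame(base, columns=[f"d{i}" for i in range(6)])
    frame["const"] = 1.0
    frame["dup_of_d0"] = frame["d0"]
    miss16 = rng.normal(size=n)
    miss16[:16] = np.nan
    frame["miss16"] = miss16
    miss15 = rng.normal(size=n)
    miss15[:15] = np.nan
    frame["miss15"] = miss15
    frame.index = pd.Index([f"c{i}" for i in range(n)], name="compound_id")
    return DescriptorMatrix(values=frame)


def test_cleaning_rules_and_boundaries():
    cleaned = clean_descriptor_matrix(_raw_matrix(), missing_limit=15)
    log = cleaned.cleaning_log
    # missing in 16 compounds > limit 15 -> dropped; exactly 15 -> kept,
    # and its 15 incomplete compounds are dropped afterwards instead
    assert log["dropped_missing_limit"] == ["miss16"]
    assert "miss15" in cleaned.descriptor_names
    assert log["dropped_incomplete_compounds"] == [f"c{i}" for i in range(15)]
    assert len(cleaned.compound_ids) == 25
    assert "const" in log["dropped_near_zero_variance"]
    # of the duplicated pair exactly one member survives
    assert ("d0" in cleaned.descriptor_names) != (
        "dup_of_d0" in cleaned.descriptor_names
    )


def test_cleaning_postconditions_hold():
    cleaned = clean_descriptor_matrix(_raw_matrix(), missing_limit=15)
    vals = cleaned.values
    assert not vals.isna().any().any()
    assert (vals.nunique() > 1).all()
    corr = vals.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    assert corr.max() <= 0.7 + 1e-12


def test_cleaning_planted_defects_in_synthetic_descriptors():
    cpds = simulate_compounds(SimulationConfig(seed=3))
    dm = simulate_descriptors(cpds, seed=3, n_constant=1, n_duplicate=1,
                              n_missing_polluted=1, missing_count=20)
    cleaned = clean_descriptor_matrix(dm)
    assert "const_01" in cleaned.cleaning_log["dropped_near_zero_variance"]
    assert cleaned.cleaning_log["dropped_missing_limit"] == ["miss_01"]
    assert not ("dup_01" in cleaned.descriptor_names
                and "info_01" in cleaned.descriptor_names)


# ------------------------------------------------------------------- training
def _training_data(seed=0, n=120):
    cfg = SimulationConfig(n_calibrants=0, n_suspects=n, seed=seed)
    cpds = simulate_compounds(cfg)
    dm = simulate_descriptors(cpds, seed=seed)
    u = np.array([c.latent_u for c in cpds])
    rng = np.random.default_rng(seed)
    rts = 2.0 + 16.0 * u + rng.normal(0, 0.2, n)
    return dm, rts


def test_train_rt_model_deterministic_under_seed():
    dm, rts = _training_data()
    m1 = train_rt_model(dm, rts, seed=7, param_grid=FAST_GRID)
    m2 = train_rt_model(dm, rts, seed=7, param_grid=FAST_GRID)
    assert np.array_equal(m1.predict(dm), m2.predict(dm))
    assert m1.retained_descriptors == m2.retained_descriptors


def test_train_rt_model_requires_minimum_n():
    dm, rts = _training_data(n=30)
    with pytest.raises(InsufficientDataError):
        train_rt_model(dm, rts, seed=0, param_grid=FAST_GRID)


def test_local_model_smoke_at_small_n():
    dm, rts = _training_data(n=12)
    model = train_local_model(dm, 1000 * (rts - rts.min()) / np.ptp(rts),
                              seed=0)
    assert np.isfinite(model.predict(dm)).all()
    with pytest.raises(InsufficientDataError):
        train_local_model(DescriptorMatrix(dm.values.iloc[:9]), rts[:9],
                          seed=0)


# ---------------------------------------------------------------- calibration
class _OracleModel:
    """Duck-typed stand-in predicting stored retention times exactly."""

    def __init__(self, mapping: dict):
        self._mapping = mapping
        self.retained_descriptors = []

    def predict(self, m: DescriptorMatrix) -> np.ndarray:
        return np.array([self._mapping[c] for c in m.compound_ids])


def _dummy_dm(ids):
    return DescriptorMatrix(pd.DataFrame(
        {"x": np.zeros(len(ids))},
        index=pd.Index(ids, name="compound_id"),
    ))


def test_perfect_model_linear_system_recovers_observed_rti():
    cal_ids = [f"C{i}" for i in range(12)]
    sus_ids = [f"S{i}" for i in range(5)]
    cal_rt = np.linspace(2.0, 14.0, 12)
    sus_rt = np.array([3.3, 5.5, 7.7, 9.9, 12.1])
    model = _OracleModel({**dict(zip(cal_ids, cal_rt)),
                          **dict(zip(sus_ids, sus_rt))})
    cal_rti = 1000 * (cal_rt - cal_rt.min()) / np.ptp(cal_rt)
    out = predict_and_calibrate(model, _dummy_dm(sus_ids),
                                _dummy_dm(cal_ids), cal_rti)
    expected = 1000 * (sus_rt - cal_rt.min()) / np.ptp(cal_rt)
    assert np.allclose(out.suspect_rti().to_numpy(), expected, atol=1.0)


def test_constant_predictor_is_degenerate():
    ids = [f"C{i}" for i in range(12)]
    model = _OracleModel({c: 5.0 for c in ids})
    with pytest.raises(DegenerateFitError):
        predict_and_calibrate(model, _dummy_dm(["S0"]), _dummy_dm(ids),
                              np.linspace(0, 1000, 12))


def test_calibration_needs_min_shared_calibrants():
    ids = [f"C{i}" for i in range(5)]
    model = _OracleModel({c: float(i) for i, c in enumerate(ids)})
    with pytest.raises(InsufficientAnchorsError):
        predict_and_calibrate(model, _dummy_dm(ids), _dummy_dm(ids),
                              np.linspace(0, 1000, 5))


def test_out_of_calibration_range_suspects_excluded():
    cal_ids = [f"C{i}" for i in range(12)]
    cal_rt = np.linspace(2.0, 14.0, 12)
    model = _OracleModel({**dict(zip(cal_ids, cal_rt)), "S0": 15.0,
                          "S1": 8.0})
    out = predict_and_calibrate(model, _dummy_dm(["S0", "S1"]),
                                _dummy_dm(cal_ids),
                                np.linspace(0, 1000, 12))
    reasons = dict(zip(out.suspects["compound_id"],
                       out.suspects["exclusion_reason"]))
    assert reasons == {"S0": "out_of_range", "S1": ""}


def test_training_rows_disjoint_from_evaluation_rows():
    """The external training table never contains the study calibrants
    or suspects."""
    from rtbridge.simulate import simulate_external_compounds
    study = simulate_compounds(SimulationConfig(seed=1))
    ext = simulate_external_compounds(200, 0.4, seed=1)
    assert {c.compound_id for c in ext}.isdisjoint(
        c.compound_id for c in study
    )
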