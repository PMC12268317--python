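"""Retention prediction from molecular descriptors.

The prediction arm trains a gradient-boosted regression-tree ensemble
on an external (structure, RT) table, with hyperparameters chosen by
five-times-repeated two-fold cross-validation, then transfers the
predictions onto each target system's RTI scale: the same penalized-
spline machinery used for pair projection maps predicted calibrant RTs
to the calibrants' observed RTIs on the target, and that calibration is
applied to the suspects.  A calibrant-only "local" variant trains the
same learner directly on one system's calibrant RTIs.

Descriptor matrices are cleaned before modelling: descriptors missing
for too many compounds are discarded, then compounds with remaining
gaps, then near-zero-variance descriptors, and finally one member of
each highly correlated descriptor pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold
from xgboost import XGBRegressor

from .errors import (DegenerateFitError, InsufficientAnchorsError,
                     InsufficientDataError)
from .gam import DEFAULT_K, fit_penalized_spline
from .rti import DEFAULT_MIN_SHARED, compute_rti

logger = logging.getLogger(__name__)

MISSING_LIMIT = 15
CORR_CUTOFF = 0.7
FREQ_RATIO_CUT = 19.0  # 95/5
UNIQUE_FRACTION_CUT = 0.10
MIN_TRAIN = 40
MIN_TRAIN_LOCAL = 10

# desk-scale hyperparameter grid for the boosted-tree learner
DEFAULT_GRID = {
    "max_depth": (3, 5, 7),
    "learning_rate": (0.05, 0.1, 0.3),
    "n_estimators": (100, 300),
    "subsample": (0.8,),
}
# single-point grid for repeated small fits (local models, seed sweeps)
FAST_GRID = {
    "max_depth": (4,),
    "learning_rate": (0.1,),
    "n_estimators": (150,),
    "subsample": (0.8,),
}


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors matrix with a log of cleaning drops."""

    values: pd.DataFrame
    cleaning_log: dict = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, ids) -> "DescriptorMatrix":
        return DescriptorMatrix(self.values.loc[list(ids)].copy(),
                                dict(self.cleaning_log))


def compute_descriptors(smiles: list[str], ids: list[str] | None = None,
                        include_3d: bool = True,
                        embed_seed: int = 42) -> DescriptorMatrix:
    """Molecular descriptors from SMILES via RDKit.

    Structures are standardized first (largest fragment, normalized
    functional groups, neutralized charges); 2D descriptors are computed
    on the standardized molecule and 3D shape descriptors on a single
    ETKDG-embedded conformer with a fixed embedding seed.  Unparseable
    SMILES yield an all-missing row and are flagged in the cleaning log,
    never fatal.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, Descriptors3D, AllChem
    from rdkit.Chem.MolStandardize import rdMolStandardize
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    if ids is None:
        ids = [f"cpd_{i + 1:04d}" for i in range(len(smiles))]
    chooser = rdMolStandardize.LargestFragmentChooser()
    uncharger = rdMolStandardize.Uncharger()

    rows, failed = [], []
    names: list[str] | None = None
    for cid, smi in zip(ids, smiles):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            failed.append(cid)
            rows.append(None)
            continue
        mol = rdMolStandardize.Cleanup(mol)
        mol = chooser.choose(mol)
        mol = uncharger.uncharge(mol)
        desc = Descriptors.CalcMolDescriptors(mol)
        if include_3d:
            mol3d = Chem.AddHs(mol)
            params = AllChem.ETKDGv3()
            params.randomSeed = embed_seed
            ok = AllChem.EmbedMolecule(mol3d, params)
            if ok == 0:
                desc.update(Descriptors3D.CalcMolDescriptors3D(mol3d))
        if names is None:
            names = list(desc)
        rows.append(desc)
    if names is None:
        raise InsufficientDataError("no parseable structures")
    data = [
        [r.get(n, np.nan) for n in names] if r is not None
        else [np.nan] * len(names)
        for r in rows
    ]
    values = pd.DataFrame(
        np.asarray(data, dtype=float),
        index=pd.Index(ids, name="compound_id"), columns=names,
    )
    return DescriptorMatrix(values=values,
                            cleaning_log={"failed_parse": failed})


def _near_zero_variance(col: pd.Series, freq_cut: float,
                        unique_cut: float) -> bool:
    counts = col.value_counts()
    if len(counts) <= 1:
        return True
    ratio = counts.iloc[0] / counts.iloc[1]
    unique_fraction = len(counts) / len(col)
    return ratio >= freq_cut and unique_fraction <= unique_cut


def clean_descriptor_matrix(m: DescriptorMatrix,
                            missing_limit: int = MISSING_LIMIT,
                            corr_cutoff: float = CORR_CUTOFF,
                            freq_cut: float = FREQ_RATIO_CUT,
                            unique_cut: float = UNIQUE_FRACTION_CUT
                            ) -> DescriptorMatrix:
    """Apply the four cleaning rules in order.

    1. drop descriptors missing for more than ``missing_limit`` compounds
       (missing for exactly the limit is kept);
    2. drop compounds with any remaining missing value;
    3. drop near-zero-variance descriptors (most/second-most frequent
       value ratio >= 19 with unique fraction <= 10%, and all constant
       columns);
    4. from each descriptor pair with |r| > ``corr_cutoff``, iteratively
       drop the member with the larger mean absolute correlation, ties
       broken by column order.
    """
    vals = m.values.copy()
    log = dict(m.cleaning_log)

    missing = vals.isna().sum(axis=0)
    drop_missing = list(missing.index[missing > missing_limit])
    vals = vals.drop(columns=drop_missing)
    log["dropped_missing_limit"] = drop_missing

    incomplete = vals.index[vals.isna().any(axis=1)]
    vals = vals.drop(index=incomplete)
    log["dropped_incomplete_compounds"] = list(incomplete)
    if vals.empty:
        raise InsufficientDataError("no compounds left after cleaning")

    nzv = [c for c in vals.columns
           if _near_zero_variance(vals[c], freq_cut, unique_cut)]
    vals = vals.drop(columns=nzv)
    log["dropped_near_zero_variance"] = nzv
    if vals.shape[1] == 0:
        raise InsufficientDataError("all descriptors dropped")

    corr = vals.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    cols = list(vals.columns)
    active = list(range(len(cols)))
    dropped_corr = []
    while True:
        sub = corr[np.ix_(active, active)]
        if sub.size == 0 or np.nanmax(sub) <= corr_cutoff:
            break
        i_s, j_s = np.unravel_index(np.nanargmax(sub), sub.shape)
        i, j = active[min(i_s, j_s)], active[max(i_s, j_s)]
        mean_i = np.nanmean(corr[i, active])
        mean_j = np.nanmean(corr[j, active])
        # larger mean absolute correlation loses; ties keep the earlier column
        victim = j if mean_j >= mean_i else i
        dropped_corr.append(cols[victim])
        active.remove(victim)
    vals = vals[[cols[i] for i in active]]
    log["dropped_correlated"] = dropped_corr
    if vals.shape[1] == 0:
        raise InsufficientDataError("all descriptors dropped")
    return DescriptorMatrix(values=vals, cleaning_log=log)


@dataclass
class RTModel:
    """Fitted boosted-tree retention model."""

    retained_descriptors: list[str]
    hyperparameters: dict
    cv_config: tuple[int, int]  # (folds, repeats)
    cv_rmse: float
    seed: int
    booster: XGBRegressor = field(repr=False, default=None)

    def predict(self, m: DescriptorMatrix | pd.DataFrame) -> np.ndarray:
        vals = m.values if isinstance(m, DescriptorMatrix) else m
        missing = set(self.retained_descriptors) - set(vals.columns)
        if missing:
            raise InsufficientDataError(
                f"descriptor matrix lacks columns: {sorted(missing)[:5]}..."
            )
        x = vals[self.retained_descriptors].to_numpy(dtype=float)
        return self.booster.predict(x).astype(float)


def _make_booster(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        **params, tree_method="hist", n_jobs=1, random_state=seed,
        verbosity=0,
    )


def _grid_points(grid: dict):
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _fit_learner(x: np.ndarray, y: np.ndarray, names: list[str], seed: int,
                 param_grid: dict | None, folds: int, repeats: int
                 ) -> RTModel:
    grid = param_grid or DEFAULT_GRID
    points = list(_grid_points(grid))
    if len(points) > 1:
        cv = RepeatedKFold(n_splits=folds, n_repeats=repeats,
                           random_state=seed)
        splits = list(cv.split(x))
        best = None
        for params in points:
            errs = []
            for tr, te in splits:
                mdl = _make_booster(params, seed)
                mdl.fit(x[tr], y[tr])
                pred = mdl.predict(x[te])
                errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
            mean_rmse = float(np.mean(errs))
            if best is None or mean_rmse < best[0]:
                best = (mean_rmse, params)
        cv_rmse, winning = best
    else:
        winning = points[0]
        cv_rmse = float("nan")
    final = _make_booster(winning, seed)
    final.fit(x, y)
    return RTModel(
        retained_descriptors=list(names),
        hyperparameters=dict(winning),
        cv_config=(folds, repeats),
        cv_rmse=cv_rmse,
        seed=seed,
        booster=final,
    )


def train_rt_model(m: DescriptorMatrix, rts, seed: int,
                   param_grid: dict | None = None,
                   folds: int = 2, repeats: int = 5,
                   min_train: int = MIN_TRAIN) -> RTModel:
    """Train the retention model on a cleaned descriptor matrix.

    Hyperparameters are selected by minimum mean RMSE over repeated
    k-fold cross-validation (the same splits for every grid point), the
    final model is refit on all data, and everything is reproducible
    from the seed.
    """
    y = np.asarray(rts, dtype=float)
    if len(m.compound_ids) != y.size:
        raise ValueError("descriptor rows and RT vector differ in length")
    if y.size < min_train:
        raise InsufficientDataError(
            f"need >= {min_train} training compounds, got {y.size}"
        )
    x = m.values.to_numpy(dtype=float)
    return _fit_learner(x, y, m.descriptor_names, seed, param_grid,
                        folds, repeats)


def train_local_model(calibrant_descriptors: DescriptorMatrix,
                      calibrant_rti, seed: int,
                      param_grid: dict | None = None,
                      folds: int = 2, repeats: int = 5) -> RTModel:
    """Calibrant-only variant: the same learner trained directly on one
    system's calibrant RTIs (small n is allowed down to 10)."""
    y = np.asarray(calibrant_rti, dtype=float)
    if y.size < MIN_TRAIN_LOCAL:
        raise InsufficientDataError(
            f"need >= {MIN_TRAIN_LOCAL} calibrants, got {y.size}"
        )
    x = calibrant_descriptors.values.to_numpy(dtype=float)
    return _fit_learner(x, y, calibrant_descriptors.descriptor_names, seed,
                        param_grid or FAST_GRID, folds, repeats)


@dataclass
class CalibratedPredictions:
    """Suspect RTI predictions after calibrant-based transfer to one
    target system's RTI scale."""

    suspects: pd.DataFrame  # compound_id, rt_predicted, rti_calibrated,
    #                         exclusion_reason
    calibrants: pd.DataFrame  # compound_id, rt_predicted, rti_fitted,
    #                           rti_observed
    calibration_range: tuple[float, float]

    def suspect_rti(self) -> pd.Series:
        d = self.suspects[self.suspects["exclusion_reason"] == ""]
        return pd.Series(d["rti_calibrated"].to_numpy(),
                         index=d["compound_id"].to_numpy())


def predict_and_calibrate(model: RTModel,
                          suspects: DescriptorMatrix,
                          calibrants: DescriptorMatrix,
                          calibrant_rti_target,
                          k: int = DEFAULT_K,
                          min_shared: int = DEFAULT_MIN_SHARED,
                          linear: bool = False) -> CalibratedPredictions:
    """Predict RTs and transfer them to the target system's RTI scale.

    The transfer fits predicted calibrant RT -> observed calibrant RTI
    with the penalized-spline smooth (or, with ``linear=True``, the
    two-anchor linear index on the predicted-RT scale).  Suspects whose
    predicted RT falls outside the calibrants' predicted-RT range are
    excluded as out of range.
    """
    rti_obs = np.asarray(calibrant_rti_target, dtype=float)
    if rti_obs.size < min_shared:
        raise InsufficientAnchorsError(
            f"need >= {min_shared} calibrants with observed RTIs, "
            f"got {rti_obs.size}"
        )
    rt_cal = model.predict(calibrants)
    if np.ptp(rt_cal) == 0:
        raise DegenerateFitError(
            "constant predictor: all calibrant RT predictions equal"
        )
    lo, hi = float(rt_cal.min()), float(rt_cal.max())
    rt_sus = model.predict(suspects)

    if linear:
        def transfer(v):
            return compute_rti(v, lo, hi)
    else:
        spline = fit_penalized_spline(rt_cal, rti_obs, k=k, bounds=(lo, hi))
        transfer = spline.predict

    in_range = (rt_sus >= lo) & (rt_sus <= hi)
    rti_sus = np.full(rt_sus.size, np.nan)
    if in_range.any():
        rti_sus[in_range] = np.atleast_1d(transfer(rt_sus[in_range]))
    reason = np.where(in_range, "", "out_of_range").astype(object)
    sus_frame = pd.DataFrame({
        "compound_id": suspects.compound_ids,
        "rt_predicted": rt_sus,
        "rti_calibrated": rti_sus,
        "exclusion_reason": reason,
    })
    cal_frame = pd.DataFrame({
        "compound_id": calibrants.compound_ids,
        "rt_predicted": rt_cal,
        "rti_fitted": np.atleast_1d(transfer(rt_cal)),
        "rti_observed": rti_obs,
    })
    return CalibratedPredictions(
        suspects=sus_frame,
        calibrants=cal_frame,
        calibration_range=(lo, hi),
    )
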