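"""GAM projection of retention time indices between system pairs.

For each ordered pair of systems a univariate penalized-spline smooth
(basis dimension 6, smoothing by GCV) maps source RTIs to target RTIs.
The model is fitted on the shared calibrants and applied to the
suspects; only suspects eluting inside the calibration range of the
source system (RTI in [0, 1000]) are projected, and evaluation is
allowed on exactly that closed interval — never beyond.  Because the
smooth minimizes residuals in the target direction, A->B and B->A are
distinct fits with possibly different accuracies, so all ordered
combinations are run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import ErrorSummary, error_summary
from .errors import (DegenerateAnchorError, DegenerateFitError,
                     InsufficientAnchorsError)
from .gam import DEFAULT_K, PenalizedSpline, fit_penalized_spline
from .io import ChromSystem, RetentionTable
from .rti import DEFAULT_MIN_SHARED, RTI_SPAN, PairRTIData, pairwise_rti

logger = logging.getLogger(__name__)

EXCLUDE_OUT_OF_RANGE = "out_of_range"
EXCLUDE_UNDETECTED = "undetected"


@dataclass
class ProjectionModel:
    """Fitted source->target RTI mapping for one ordered pair."""

    cs_source: str
    cs_target: str
    basis_dimension: int
    spline: PenalizedSpline
    n_train: int

    @property
    def smoothing_parameter(self) -> float:
        return self.spline.smoothing_parameter

    @property
    def train_range(self) -> tuple[float, float]:
        return self.spline.train_range

    def is_monotone(self, n_grid: int = 201) -> bool:
        grid = np.linspace(0.0, RTI_SPAN, n_grid)
        return bool(np.all(np.diff(self.spline.predict(grid)) >= 0))


def fit_projection_gam(pair: PairRTIData, k: int = DEFAULT_K,
                       min_shared: int = DEFAULT_MIN_SHARED,
                       warn_non_monotone: bool = False) -> ProjectionModel:
    """Fit the calibrant smooth for one pair.

    The basis spans the full RTI domain [0, 1000] so in-range suspects
    can always be evaluated, including at the boundaries.
    """
    if pair.n_shared < min_shared:
        raise InsufficientAnchorsError(
            f"{pair.cs_source}->{pair.cs_target}: {pair.n_shared} shared "
            f"calibrants < min_shared={min_shared}"
        )
    x = pair.calibrants["rti_source"].to_numpy(dtype=float)
    y = pair.calibrants["rti_target"].to_numpy(dtype=float)
    spline = fit_penalized_spline(x, y, k=k, bounds=(0.0, RTI_SPAN))
    model = ProjectionModel(
        cs_source=pair.cs_source,
        cs_target=pair.cs_target,
        basis_dimension=k,
        spline=spline,
        n_train=pair.n_shared,
    )
    if warn_non_monotone and not model.is_monotone():
        logger.warning("%s->%s: fitted projection is non-monotone on "
                       "[0, 1000]", pair.cs_source, pair.cs_target)
    return model


def project_rti(model: ProjectionModel, rti_source) -> pd.DataFrame:
    """Evaluate the projection on source RTIs.

    Returns a frame with columns ``rti_source``, ``rti_projected`` (NaN
    where excluded) and ``exclusion_reason`` (empty string where
    projected).  Sources outside [0, 1000] are excluded as
    ``out_of_range`` rather than extrapolated.
    """
    x = np.atleast_1d(np.asarray(rti_source, dtype=float))
    projected = np.full(x.size, np.nan)
    reason = np.array([""] * x.size, dtype=object)
    undet = ~np.isfinite(x)
    reason[undet] = EXCLUDE_UNDETECTED
    in_range = np.isfinite(x) & (x >= 0.0) & (x <= RTI_SPAN)
    reason[np.isfinite(x) & ~in_range] = EXCLUDE_OUT_OF_RANGE
    if in_range.any():
        projected[in_range] = model.spline.predict(x[in_range])
    return pd.DataFrame(
        {"rti_source": x, "rti_projected": projected,
         "exclusion_reason": reason}
    )


@dataclass
class ProjectionResult:
    """Per-pair projection outcome: suspect-level detail plus pre- and
    post-GAM error summaries (pre-GAM error = observed target RTI minus
    source RTI, the shared-anchor baseline without any model)."""

    cs_source: str
    cs_target: str
    n_shared_calibrants: int
    suspects: pd.DataFrame
    excluded: pd.DataFrame  # columns compound_id, reason
    error_summary_pre_gam: ErrorSummary | None
    error_summary_post_gam: ErrorSummary | None
    error_summary_calibrants: ErrorSummary | None
    model: ProjectionModel | None = None

    def to_record(self) -> dict:
        rec = {
            "cs_source": self.cs_source,
            "cs_target": self.cs_target,
            "n_shared_calibrants": self.n_shared_calibrants,
            "n_suspects": len(self.suspects),
            "n_excluded": len(self.excluded),
        }
        for prefix, summ in (
            ("pre_", self.error_summary_pre_gam),
            ("post_", self.error_summary_post_gam),
            ("cal_", self.error_summary_calibrants),
        ):
            if summ is None:
                rec.update({f"{prefix}{f}": np.nan
                            for f in ("n", "rmse", "mad", "p95", "r2")})
            else:
                rec.update(summ.to_record(prefix))
        return rec

    def suspect_residuals(self) -> dict:
        """Post-GAM residuals keyed by compound_id (evaluated suspects)."""
        d = self.suspects.dropna(subset=["rti_projected",
                                         "rti_observed_target"])
        return dict(zip(
            d["compound_id"],
            d["rti_projected"] - d["rti_observed_target"],
        ))


def project_pair(pair: PairRTIData, k: int = DEFAULT_K,
                 min_shared: int = DEFAULT_MIN_SHARED,
                 include_out_of_range_targets: bool = True,
                 keep_model: bool = False) -> ProjectionResult:
    """Fit, project and score one ordered pair."""
    model = fit_projection_gam(pair, k=k, min_shared=min_shared)

    sus = pair.suspects.copy()
    proj = project_rti(model, sus["rti_source"].to_numpy())
    sus["rti_projected"] = proj["rti_projected"].to_numpy()
    sus["exclusion_reason"] = proj["exclusion_reason"].to_numpy()
    sus = sus.rename(columns={"rti_target": "rti_observed_target"})

    # suspects undetected on the target cannot be evaluated
    no_target = sus["rti_observed_target"].isna() & (
        sus["exclusion_reason"] == ""
    )
    sus.loc[no_target, "exclusion_reason"] = EXCLUDE_UNDETECTED
    if not include_out_of_range_targets:
        oot = ~sus["in_range_target"] & (sus["exclusion_reason"] == "")
        sus.loc[oot, "exclusion_reason"] = EXCLUDE_OUT_OF_RANGE

    eval_mask = sus["exclusion_reason"] == ""
    sus["abs_dev"] = np.where(
        eval_mask,
        np.abs(sus["rti_projected"] - sus["rti_observed_target"]),
        np.nan,
    )
    excluded = sus.loc[~eval_mask, ["compound_id", "exclusion_reason"]]
    excluded = excluded.rename(columns={"exclusion_reason": "reason"})

    ev = sus[eval_mask]
    pre = post = None
    if len(ev):
        pre = error_summary(
            ev["rti_observed_target"] - ev["rti_source"],
            predicted=ev["rti_source"], observed=ev["rti_observed_target"],
        )
        post = error_summary(
            ev["rti_observed_target"] - ev["rti_projected"],
            predicted=ev["rti_projected"],
            observed=ev["rti_observed_target"],
        )
    cal_fit = model.spline.predict(
        pair.calibrants["rti_source"].to_numpy()
    )
    cal = error_summary(
        pair.calibrants["rti_target"].to_numpy() - cal_fit,
        predicted=cal_fit, observed=pair.calibrants["rti_target"],
    )
    return ProjectionResult(
        cs_source=pair.cs_source,
        cs_target=pair.cs_target,
        n_shared_calibrants=pair.n_shared,
        suspects=sus,
        excluded=excluded.reset_index(drop=True),
        error_summary_pre_gam=pre,
        error_summary_post_gam=post,
        error_summary_calibrants=cal,
        model=model if keep_model else None,
    )


def run_all_pairs(table: RetentionTable,
                  systems: list[ChromSystem] | None = None,
                  k: int = DEFAULT_K,
                  min_shared: int = DEFAULT_MIN_SHARED,
                  include_out_of_range_targets: bool = True):
    """Project every ordered pair of (RP) systems.

    Returns ``(results, skipped)`` where ``skipped`` is a list of
    ``(cs_source, cs_target, reason)``.  Non-RP systems are excluded up
    front because projection assumes a shared retention mechanism.
    """
    if systems is not None:
        keep = [s.cs_id for s in systems if s.mechanism == "RP"]
        dropped = [s.cs_id for s in systems if s.mechanism != "RP"]
        if dropped:
            logger.info("excluding non-RP systems: %s", dropped)
        cs_ids = [c for c in table.system_ids if c in keep]
    else:
        cs_ids = table.system_ids
    if len(cs_ids) < 2:
        raise InsufficientAnchorsError("need >= 2 RP systems")
    results, skipped = [], []
    for src in cs_ids:
        for tgt in cs_ids:
            if src == tgt:
                continue
            try:
                pair = pairwise_rti(table, src, tgt, min_shared=min_shared)
                results.append(project_pair(
                    pair, k=k, min_shared=min_shared,
                    include_out_of_range_targets=include_out_of_range_targets,
                ))
            except (InsufficientAnchorsError, DegenerateAnchorError,
                    DegenerateFitError) as exc:
                logger.warning("skipping %s->%s: %s", src, tgt, exc)
                skipped.append((src, tgt, str(exc)))
    return results, skipped
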