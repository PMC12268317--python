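"""Error summaries and statistical comparison of two error sets.

Accuracy of a projection or prediction is summarized by the RMSE, the
mean absolute deviation (MAD) and the 95th percentile of absolute
deviations of predicted vs observed RTIs.  Two methods are compared on a
common compound set by an F-test on the ratio of mean squared errors
(two-sided, p < alpha, no multiple-testing correction), with degrees of
freedom equal to the residual counts — residuals here are prediction
errors, not deviations from a fitted mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

DEFAULT_ALPHA = 0.05
MIN_COMMON = 3


@dataclass
class ErrorSummary:
    n: int
    rmse: float
    mad: float
    p95_abs_dev: float
    r2: float | None = None

    def to_record(self, prefix: str = "") -> dict:
        rec = {
            f"{prefix}n": self.n,
            f"{prefix}rmse": self.rmse,
            f"{prefix}mad": self.mad,
            f"{prefix}p95": self.p95_abs_dev,
        }
        rec[f"{prefix}r2"] = np.nan if self.r2 is None else self.r2
        return rec


def error_summary(residuals, predicted=None, observed=None) -> ErrorSummary:
    """RMSE, MAD and P95 of |residual|; optional R^2 of predicted vs
    observed (squared Pearson correlation) when both vectors are given."""
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise InsufficientDataError("no residuals to summarize")
    r2 = None
    if predicted is not None and observed is not None:
        p = np.asarray(predicted, dtype=float)
        o = np.asarray(observed, dtype=float)
        ok = np.isfinite(p) & np.isfinite(o)
        if ok.sum() >= 3 and np.ptp(p[ok]) > 0 and np.ptp(o[ok]) > 0:
            r2 = float(stats.pearsonr(p[ok], o[ok]).statistic ** 2)
    return ErrorSummary(
        n=int(r.size),
        rmse=float(np.sqrt(np.mean(r**2))),
        mad=float(np.mean(np.abs(r))),
        p95_abs_dev=float(np.percentile(np.abs(r), 95)),
        r2=r2,
    )


def f_test_rmse(residuals_a, residuals_b, alpha: float = DEFAULT_ALPHA):
    """Two-sided F-test comparing mean squared prediction errors.

    F = MSE_larger / MSE_smaller with df = (n_larger, n_smaller);
    p = 2 * min(tail probabilities), capped at 1.  Returns
    ``(f_statistic, p_value, significant)``.
    """
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 residuals per method")
    mse_a = np.mean(a**2)
    mse_b = np.mean(b**2)
    if mse_a == 0 and mse_b == 0:
        return 1.0, 1.0, False
    if mse_a == 0 or mse_b == 0:
        # one method is exact: the variance ratio is degenerate
        return np.inf, 0.0, True
    if mse_a >= mse_b:
        f, dfn, dfd = mse_a / mse_b, a.size, b.size
    else:
        f, dfn, dfd = mse_b / mse_a, b.size, a.size
    p = min(1.0, 2.0 * min(stats.f.cdf(f, dfn, dfd),
                           stats.f.sf(f, dfn, dfd)))
    return float(f), float(p), bool(p < alpha)


@dataclass
class ComparisonRecord:
    """Projection-vs-prediction verdict for one ordered system pair,
    restricted to suspects for which both methods produced an RTI."""

    cs_source: str
    cs_target: str
    n_common_suspects: int
    rmse_projection: float
    rmse_prediction: float
    f_statistic: float
    p_value: float
    verdict: str  # projection_better | prediction_better | indistinguishable
    excluded: bool = False
    reason: str = ""

    def to_record(self) -> dict:
        return {
            "cs_source": self.cs_source,
            "cs_target": self.cs_target,
            "n_common_suspects": self.n_common_suspects,
            "rmse_projection": self.rmse_projection,
            "rmse_prediction": self.rmse_prediction,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "excluded": self.excluded,
            "reason": self.reason,
        }


def classify_pair(cs_source: str, cs_target: str,
                  proj_residuals: dict, pred_residuals: dict,
                  alpha: float = DEFAULT_ALPHA) -> ComparisonRecord:
    """Compare projection and prediction residuals (dicts keyed by
    compound_id) on their common suspect set."""
    common = sorted(set(proj_residuals) & set(pred_residuals))
    if len(common) < MIN_COMMON:
        return ComparisonRecord(
            cs_source, cs_target, len(common), np.nan, np.nan, np.nan,
            np.nan, "excluded", excluded=True,
            reason=f"only {len(common)} common suspects",
        )
    rp = np.array([proj_residuals[c] for c in common], dtype=float)
    rq = np.array([pred_residuals[c] for c in common], dtype=float)
    rmse_p = float(np.sqrt(np.mean(rp**2)))
    rmse_q = float(np.sqrt(np.mean(rq**2)))
    f, p, sig = f_test_rmse(rp, rq, alpha)
    if not sig:
        verdict = "indistinguishable"
    elif rmse_p < rmse_q:
        verdict = "projection_better"
    else:
        verdict = "prediction_better"
    return ComparisonRecord(
        cs_source, cs_target, len(common), rmse_p, rmse_q, f, p, verdict
    )


def aggregate_comparison(records) -> dict:
    """Counts and fractions per verdict over the usable comparison pairs."""
    records = list(records)
    if not records:
        raise InsufficientDataError("no comparison records")
    usable = [r for r in records if not r.excluded]
    n = len(usable)
    counts = {
        v: sum(1 for r in usable if r.verdict == v)
        for v in ("projection_better", "prediction_better",
                  "indistinguishable")
    }
    out = {
        "n_pairs": n,
        "n_excluded": len(records) - n,
        "counts": counts,
        "fractions": {k: (v / n if n else np.nan)
                      for k, v in counts.items()},
    }
    return out


def fraction_improved(pre_rmse, post_rmse) -> float:
    """Fraction of pairs whose RMSE point estimate dropped after the
    projection model was applied."""
    pre = np.asarray(pre_rmse, dtype=float)
    post = np.asarray(post_rmse, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    if not ok.any():
        raise InsufficientDataError("no pairs with both RMSEs")
    return float(np.mean(post[ok] < pre[ok]))
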