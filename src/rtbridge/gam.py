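"""Univariate penalized-spline smoother with GCV smoothing selection.

The workhorse behind both the pair projection and the predicted-RT
calibration: a cubic B-spline basis of fixed dimension ``k`` (intercept
plus k-1 spline columns) with a second-derivative roughness penalty,

    min_beta ||y - X beta||^2 + lam * beta' S beta,

solved in closed form on a fixed logarithmic grid of smoothing
parameters; ``lam`` is chosen by generalized cross-validation,
GCV(lam) = n * RSS / (n - edf)^2.  The fit minimizes residuals in the
response direction only, so fitting A->B is not the inverse of B->A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.gam.smooth_basis import BSplines

from .errors import DegenerateFitError

DEFAULT_K = 6
# wide fixed grid; the basis lives on an O(1000)-wide domain so optimal
# penalties can be large
LAMBDA_GRID = np.logspace(-4.0, 9.0, 40)


@dataclass
class PenalizedSpline:
    """Fitted penalized cubic regression spline y = f(x)."""

    k: int
    bounds: tuple[float, float]
    coefficients: np.ndarray
    smoothing_parameter: float
    edf: float
    gcv: float
    train_range: tuple[float, float]
    _basis: BSplines = field(repr=False)

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.bounds
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError(
                f"prediction outside the spline domain [{lo}, {hi}]"
            )
        basis = self._basis.transform(
            np.clip(x, lo, hi)[:, None]
        )
        design = np.column_stack([np.ones(x.size), basis])
        return design @ self.coefficients

    def __call__(self, x) -> np.ndarray:
        return self.predict(x)


def fit_penalized_spline(x, y, k: int = DEFAULT_K,
                         bounds: tuple[float, float] | None = None,
                         lambdas=LAMBDA_GRID) -> PenalizedSpline:
    """Fit f so that y ~ f(x), choosing the penalty by GCV.

    ``bounds`` fixes the basis domain (and the admissible prediction
    range); it must cover the training x.  Defaults to the training
    range itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size <= k:
        raise DegenerateFitError(
            f"need more than k={k} points to fit, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError("all x values identical: singular basis")
    if bounds is None:
        bounds = (float(x.min()), float(x.max()))
    lo, hi = bounds
    if x.min() < lo - 1e-6 or x.max() > hi + 1e-6:
        raise ValueError("bounds must cover the training x range")
    x = np.clip(x, lo, hi)  # absorb boundary roundoff

    bs = BSplines(
        x[:, None], df=[k], degree=[3],
        knot_kwds=[dict(lower_bound=lo, upper_bound=hi)],
    )
    design = np.column_stack([np.ones(x.size), bs.basis])
    p = design.shape[1]
    pen = np.zeros((p, p))
    pen[1:, 1:] = bs.smoothers[0].cov_der2

    xtx = design.T @ design
    xty = design.T @ y
    n = x.size
    best = None
    for lam in np.asarray(lambdas, dtype=float):
        a = xtx + lam * pen
        try:
            beta = np.linalg.solve(a, xty)
            edf = float(np.trace(np.linalg.solve(a, xtx)))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DegenerateFitError("singular penalized system") from exc
        rss = float(np.sum((y - design @ beta) ** 2))
        denom = n - edf
        if denom <= 0:
            continue
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise DegenerateFitError("GCV undefined on the whole lambda grid")
    gcv, lam, beta, edf = best
    return PenalizedSpline(
        k=k,
        bounds=(lo, hi),
        coefficients=beta,
        smoothing_parameter=float(lam),
        edf=edf,
        gcv=gcv,
        train_range=(float(x.min()), float(x.max())),
        _basis=bs,
    )
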