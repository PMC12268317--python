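"""Peak spacing along each system's elution program.

Retention times are normalized relative to the length of the elution
program (x1000, so the scale reads like an index: 500 = halfway through
the run).  The spread of the normalized values — their standard
deviation and empirical cumulative distribution — summarizes how evenly
a program distributes the compound panel: a uniform staircase means
well-spread peaks, a steep early rise means crowding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import ChromSystem, RetentionTable

NORM_SPAN = 1000.0


def normalize_rts(rts, run_time: float):
    """Scale retention times to index units: 1000 * rt / run_time."""
    if not run_time > 0:
        raise ValidationError("run_time must be > 0")
    rts = np.asarray(rts, dtype=float)
    finite = rts[np.isfinite(rts)]
    if np.any(finite <= 0):
        raise ValidationError("retention times must be > 0")
    if np.any(finite > run_time * (1 + 1e-9)):
        raise ValidationError(
            "retention time exceeds the elution program length"
        )
    out = NORM_SPAN * rts / run_time
    return float(out) if out.ndim == 0 else out


@dataclass
class SpacingSummary:
    cs_id: str
    n_detected: int
    normalized_rts: np.ndarray
    sd_normalized: float
    cumulative_curve: pd.DataFrame  # columns: normalized_rt, fraction
    max_normalized: float


def spacing_summary(table: RetentionTable, system: ChromSystem
                    ) -> SpacingSummary:
    """Normalized-RT spread for one system (calibrants and suspects).

    Uses the sample (n-1) standard deviation and the empirical CDF
    evaluated at each observed value.
    """
    rts = table.rts(system.cs_id).dropna().to_numpy(dtype=float)
    if rts.size < 2:
        raise InsufficientDataError(
            f"{system.cs_id}: need >= 2 detections, got {rts.size}"
        )
    norm = np.sort(normalize_rts(rts, system.run_time))
    frac = np.arange(1, norm.size + 1) / norm.size
    curve = pd.DataFrame({"normalized_rt": norm, "fraction": frac})
    return SpacingSummary(
        cs_id=system.cs_id,
        n_detected=int(rts.size),
        normalized_rts=norm,
        sd_normalized=float(np.std(norm, ddof=1)),
        cumulative_curve=curve,
        max_normalized=float(norm.max()),
    )
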