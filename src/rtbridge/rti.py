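"""Retention time indices (RTIs) per ordered system pair.

An RTI rescales a retention time linearly between the earliest and latest
calibrant so that calibrants span 0-1000 regardless of run length, flow
rate or column dimensions:

    RTI = 1000 * (RT - RT_min) / (RT_max - RT_min)

where RT_min and RT_max are the minimum and maximum retention times of
the calibrants *shared* by the two systems under comparison.  Because the
detected calibrant set differs from system to system, anchors are
recomputed for every ordered pair from the shared calibrants only.
Suspects may fall outside the calibrant window and then carry RTIs
outside [0, 1000]; they are flagged rather than clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateAnchorError, InsufficientAnchorsError
from .io import RetentionTable

logger = logging.getLogger(__name__)

RTI_SPAN = 1000.0
DEFAULT_MIN_SHARED = 8


def compute_rti(rt, rt_min: float, rt_max: float):
    """Two-anchor linear retention index, scalar or array.

    Values outside the anchor window extrapolate linearly (suspects may
    legitimately index below 0 or above 1000).
    """
    if not rt_max > rt_min:
        raise DegenerateAnchorError(
            f"rt_max ({rt_max}) must exceed rt_min ({rt_min})"
        )
    rt = np.asarray(rt, dtype=float)
    out = RTI_SPAN * (rt - rt_min) / (rt_max - rt_min)
    return float(out) if out.ndim == 0 else out


def in_rti_range(rti) -> np.ndarray:
    rti = np.asarray(rti, dtype=float)
    return (rti >= 0.0) & (rti <= RTI_SPAN)


@dataclass
class PairRTIData:
    """RTIs for one ordered system pair anchored on shared calibrants.

    ``calibrants`` has columns (compound_id, rti_source, rti_target);
    ``suspects`` adds ``in_range_source``/``in_range_target`` flags and may
    carry NaN ``rti_target`` for suspects undetected on the target.
    """

    cs_source: str
    cs_target: str
    shared_calibrant_ids: list[str]
    anchors_source: tuple[float, float]
    anchors_target: tuple[float, float]
    calibrants: pd.DataFrame
    suspects: pd.DataFrame

    @property
    def n_shared(self) -> int:
        return len(self.shared_calibrant_ids)


def pairwise_rti(table: RetentionTable, cs_source: str, cs_target: str,
                 min_shared: int = DEFAULT_MIN_SHARED) -> PairRTIData:
    """Build :class:`PairRTIData` for one ordered system pair.

    Only calibrants detected on *both* systems anchor the index — a
    calibrant seen on just one side is excluded from the anchors of both.
    All suspects detected on the source are converted (the projection
    input); where also detected on the target, the target RTI is recorded
    for evaluation.
    """
    shared = table.shared_detected(cs_source, cs_target, role="calibrant")
    if len(shared) < min_shared:
        raise InsufficientAnchorsError(
            f"{cs_source}->{cs_target}: {len(shared)} shared calibrants "
            f"< min_shared={min_shared}"
        )
    rt_s = table.rts(cs_source)
    rt_t = table.rts(cs_target)
    anc_s = (float(rt_s[shared].min()), float(rt_s[shared].max()))
    anc_t = (float(rt_t[shared].min()), float(rt_t[shared].max()))
    if not anc_s[1] > anc_s[0]:
        raise DegenerateAnchorError(f"{cs_source}: calibrant anchors collapse")
    if not anc_t[1] > anc_t[0]:
        raise DegenerateAnchorError(f"{cs_target}: calibrant anchors collapse")

    cal = pd.DataFrame(
        {
            "compound_id": shared,
            "rti_source": compute_rti(rt_s[shared].to_numpy(), *anc_s),
            "rti_target": compute_rti(rt_t[shared].to_numpy(), *anc_t),
        }
    )

    sus_ids = [
        c for c in table.suspect_ids if np.isfinite(rt_s.get(c, np.nan))
    ]
    rti_src = compute_rti(rt_s[sus_ids].to_numpy(), *anc_s) if sus_ids else []
    rti_tgt = np.array(
        [
            compute_rti(rt_t[c], *anc_t) if np.isfinite(rt_t[c]) else np.nan
            for c in sus_ids
        ]
    ) if sus_ids else []
    sus = pd.DataFrame(
        {
            "compound_id": sus_ids,
            "rti_source": rti_src,
            "rti_target": rti_tgt,
        }
    )
    sus["in_range_source"] = in_rti_range(sus["rti_source"]) if len(sus) else []
    sus["in_range_target"] = (
        sus["rti_target"].notna() & in_rti_range(sus["rti_target"].fillna(-1))
        if len(sus)
        else []
    )
    return PairRTIData(
        cs_source=cs_source,
        cs_target=cs_target,
        shared_calibrant_ids=list(shared),
        anchors_source=anc_s,
        anchors_target=anc_t,
        calibrants=cal,
        suspects=sus,
    )


def system_rti(table: RetentionTable, cs_id: str) -> pd.Series:
    """RTIs of all detected compounds on one system, anchored on that
    system's own detected calibrants (single-system scale, used by the
    prediction arm)."""
    rt = table.rts(cs_id)
    cal = [c for c in table.calibrant_ids if np.isfinite(rt[c])]
    if len(cal) < 2:
        raise InsufficientAnchorsError(
            f"{cs_id}: need >= 2 detected calibrants for a system RTI scale"
        )
    rt_min, rt_max = float(rt[cal].min()), float(rt[cal].max())
    if not rt_max > rt_min:
        raise DegenerateAnchorError(f"{cs_id}: calibrant anchors collapse")
    detected = table.detected(cs_id)
    return pd.Series(
        compute_rti(rt[detected].to_numpy(), rt_min, rt_max),
        index=pd.Index(detected, name="compound_id"),
        name=f"rti_{cs_id}",
    )
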