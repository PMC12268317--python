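"""Tabular data model for multi-system retention data.

The entry point of every analysis is a wide table of retention times
(minutes) for a shared compound panel measured across several
chromatographic systems (CSs), plus per-system metadata including the
gradient program.  Retention-time columns follow the ``rt_<cs_id>``
naming convention so joins across modules are unambiguous.  Missing
retention times (a compound not detected on a system) are empty cells in
CSV and ``NaN`` internally — never zero or a negative sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ROLES = ("calibrant", "suspect")
MECHANISMS = ("RP", "HILIC", "mixed")
ADDITIVE_CLASSES = ("formic_acid", "ammonium_salt", "mixed")

RT_PREFIX = "rt_"


class GradientSegment(NamedTuple):
    """One segment of a gradient program.

    ``t_start``/``t_end`` are minutes from injection; ``phi_start``/
    ``phi_end`` are organic-modifier fractions in [0, 1].  A segment with
    equal fractions is isocratic.
    """

    t_start: float
    t_end: float
    phi_start: float
    phi_end: float


@dataclass(frozen=True)
class ChromSystem:
    """Metadata for one chromatographic system.

    Parameters
    ----------
    cs_id
        Unique system identifier.
    mechanism
        Retention mechanism: ``RP``, ``HILIC`` or ``mixed``.  Projection
        and prediction assume a shared mechanism, so non-RP systems are
        filtered out before pairwise analysis.
    column_chemistry
        Stationary phase, e.g. ``C18``, ``C8``, ``biphenyl``.
    additive_class
        Mobile-phase additive family controlling aqueous-phase pH:
        ``formic_acid`` (acidic), ``ammonium_salt`` (buffered, higher pH)
        or ``mixed``.
    run_time
        Total length of the elution program, minutes.
    gradient_segments
        Contiguous, non-overlapping segments covering (0, run_time].
    """

    cs_id: str
    mechanism: str
    column_chemistry: str
    additive_class: str
    run_time: float
    gradient_segments: tuple[GradientSegment, ...]

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"{self.cs_id}: unknown mechanism {self.mechanism!r}"
            )
        if self.additive_class not in ADDITIVE_CLASSES:
            raise ValidationError(
                f"{self.cs_id}: unknown additive class {self.additive_class!r}"
            )
        if not self.run_time > 0:
            raise ValidationError(f"{self.cs_id}: run_time must be > 0")
        segs = tuple(GradientSegment(*s) for s in self.gradient_segments)
        object.__setattr__(self, "gradient_segments", segs)
        if not segs:
            raise ValidationError(f"{self.cs_id}: no gradient segments")
        tol = 1e-9
        if abs(segs[0].t_start) > tol:
            raise ValidationError(f"{self.cs_id}: program must start at t=0")
        for prev, cur in zip(segs, segs[1:]):
            if cur.t_start < prev.t_end - tol:
                raise ValidationError(f"{self.cs_id}: overlapping segments")
            if cur.t_start > prev.t_end + tol:
                raise ValidationError(f"{self.cs_id}: gap between segments")
        if abs(segs[-1].t_end - self.run_time) > tol:
            raise ValidationError(
                f"{self.cs_id}: segments end at {segs[-1].t_end}, "
                f"run_time is {self.run_time} (gap)"
            )
        for s in segs:
            if s.t_end <= s.t_start:
                raise ValidationError(f"{self.cs_id}: segment of zero length")
            if not (0 <= s.phi_start <= 1 and 0 <= s.phi_end <= 1):
                raise ValidationError(
                    f"{self.cs_id}: organic fractions must lie in [0, 1]"
                )

    @property
    def gradient_fraction(self) -> float:
        """Fraction of run time spent in non-isocratic segments."""
        grad = sum(
            s.t_end - s.t_start
            for s in self.gradient_segments
            if abs(s.phi_end - s.phi_start) > 1e-12
        )
        return grad / self.run_time

    def to_record(self) -> dict:
        return {
            "cs_id": self.cs_id,
            "mechanism": self.mechanism,
            "column_chemistry": self.column_chemistry,
            "additive_class": self.additive_class,
            "run_time": self.run_time,
            "gradient": json.dumps(
                [list(s) for s in self.gradient_segments]
            ),
        }


@dataclass
class RetentionTable:
    """Compounds x systems retention-time matrix with roles and identifiers.

    ``meta`` is indexed by compound_id with columns ``role``, ``smiles``,
    ``inchikey``; ``rt`` is indexed by compound_id with one float column
    per system id (NaN = not detected).
    """

    meta: pd.DataFrame
    rt: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            dups = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValidationError(f"duplicate compound_id: {dups}")
        bad_roles = set(self.meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown role labels: {sorted(bad_roles)}")
        if self.rt.shape[1] < 2:
            raise ValidationError("need at least 2 systems")
        if not self.rt.index.equals(self.meta.index):
            raise ValidationError("rt and meta indices differ")
        vals = self.rt.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValidationError("retention times must be > 0 or missing")

    # -- accessors ---------------------------------------------------------
    @property
    def system_ids(self) -> list[str]:
        return list(self.rt.columns)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.meta.index)

    def ids_with_role(self, role: str) -> list[str]:
        return list(self.meta.index[self.meta["role"] == role])

    @property
    def calibrant_ids(self) -> list[str]:
        return self.ids_with_role("calibrant")

    @property
    def suspect_ids(self) -> list[str]:
        return self.ids_with_role("suspect")

    def rts(self, cs_id: str) -> pd.Series:
        """Retention times on one system (NaN where undetected)."""
        return self.rt[cs_id]

    def detected(self, cs_id: str) -> list[str]:
        s = self.rt[cs_id]
        return list(s.index[s.notna()])

    def shared_detected(self, cs_a: str, cs_b: str,
                        role: str | None = None) -> list[str]:
        mask = self.rt[cs_a].notna() & self.rt[cs_b].notna()
        if role is not None:
            mask &= self.meta["role"] == role
        return list(self.rt.index[mask])

    def subset_systems(self, cs_ids: Sequence[str]) -> "RetentionTable":
        return RetentionTable(self.meta.copy(), self.rt[list(cs_ids)].copy())

    # -- (de)serialisation -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        wide = self.meta.copy()
        for cs in self.rt.columns:
            wide[RT_PREFIX + cs] = self.rt[cs]
        return wide.reset_index().rename(columns={"index": "compound_id"})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RetentionTable":
        if "compound_id" not in frame.columns:
            raise ValidationError("missing compound_id column")
        if frame["compound_id"].duplicated().any():
            dups = frame.loc[
                frame["compound_id"].duplicated(), "compound_id"
            ].tolist()
            raise ValidationError(f"duplicate compound_id: {dups}")
        frame = frame.set_index("compound_id")
        if "role" not in frame.columns:
            raise ValidationError("missing role column")
        rt_cols = [c for c in frame.columns if c.startswith(RT_PREFIX)]
        meta_cols = ["role"] + [
            c for c in ("smiles", "inchikey") if c in frame.columns
        ]
        meta = frame[meta_cols].copy()
        for c in ("smiles", "inchikey"):
            if c not in meta.columns:
                meta[c] = ""
        meta[["smiles", "inchikey"]] = (
            meta[["smiles", "inchikey"]].fillna("").astype(str)
        )
        rt = pd.DataFrame(index=frame.index)
        for c in rt_cols:
            try:
                rt[c[len(RT_PREFIX):]] = pd.to_numeric(frame[c])
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"non-numeric RT in column {c}") from exc
        return cls(meta, rt)


def read_rt_table(path: str | Path) -> RetentionTable:
    """Read a wide compounds CSV (compound_id, role, smiles, inchikey,
    rt_<cs_id>...) into a validated :class:`RetentionTable`."""
    frame = pd.read_csv(path, dtype={"compound_id": str, "role": str})
    return RetentionTable.from_frame(frame)


def write_rt_table(table: RetentionTable, path: str | Path) -> None:
    write_table(table.to_frame(), path, keys=["compound_id"])


def read_cs_metadata(path: str | Path) -> list[ChromSystem]:
    """Read per-system metadata from CSV (gradient as a JSON string column)
    or from a JSON list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    systems = []
    for rec in records:
        segs = rec["gradient"]
        if isinstance(segs, str):
            segs = json.loads(segs)
        systems.append(
            ChromSystem(
                cs_id=str(rec["cs_id"]),
                mechanism=rec["mechanism"],
                column_chemistry=rec["column_chemistry"],
                additive_class=rec["additive_class"],
                run_time=float(rec["run_time"]),
                gradient_segments=tuple(GradientSegment(*s) for s in segs),
            )
        )
    ids = [s.cs_id for s in systems]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate cs_id in system metadata")
    return systems


def write_cs_metadata(systems: Iterable[ChromSystem], path: str | Path) -> None:
    frame = pd.DataFrame([s.to_record() for s in systems])
    write_table(frame, path, keys=["cs_id"])


def write_table(rows, path: str | Path, keys: Sequence[str] | None = None
                ) -> None:
    """Write a tabular result as deterministic UTF-8 CSV.

    Rows are sorted by ``keys`` (all columns if omitted) so repeated runs
    produce byte-identical files; floats round-trip at full precision.
    """
    if isinstance(rows, RetentionTable):
        frame = rows.to_frame()
        keys = keys or ["compound_id"]
    else:
        frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError(f"refusing to write empty table to {path}")
    sort_cols = list(keys) if keys else list(frame.columns)
    frame = frame.sort_values(sort_cols, kind="mergesort")
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
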