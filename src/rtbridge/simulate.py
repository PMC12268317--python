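"""Synthetic interlaboratory retention data with known ground truth.

Each compound carries a one-dimensional latent elution coordinate
``u`` in (0, 1) — a log-hydrophobicity surrogate.  A chromatographic
system turns ``u`` into a retention time through a strictly monotone
piecewise-linear warp derived from its gradient program: steep gradient
segments spread elution out, isocratic holds and plateaus compress it.
Ionizable compounds shift in latent space on systems whose mobile-phase
additive raises the aqueous pH (ammonium salts): bases elute later,
acids earlier.  Gaussian measurement noise and independent per-compound
detection dropout complete the emulation.  The generator records the
full truth (coordinates, warps, shifts) so downstream analyses can be
checked against it exactly.

Reproducibility: one global seed fans out to per-component streams via
a fixed counter scheme (``SeedSequence([seed, stream])``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ChromSystem, GradientSegment, RetentionTable
from .prediction import DescriptorMatrix

# fixed stream ids for the seed fan-out
_STREAM_COMPOUNDS = 0
_STREAM_SYSTEMS = 1
_STREAM_NOISE = 2
_STREAM_DROPOUT = 3
_STREAM_DESCRIPTORS = 4
_STREAM_EXTERNAL = 5
_STREAM_TRAINING_NOISE = 6

ION_CLASSES = ("neutral", "acid", "base")
PKA_RANGE = (3.6, 8.1)
DEAD_TIME_FLOOR = 0.5  # minutes
ISOCRATIC_BASELINE = 0.05  # fraction of elution progress per unit time share


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    role: str  # calibrant | suspect | external
    latent_u: float
    ion_class: str
    pka: float  # NaN for neutrals

    @property
    def ion_sign(self) -> int:
        return {"neutral": 0, "acid": -1, "base": 1}[self.ion_class]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic interlaboratory campaign.

    Defaults emulate the interlab layout: 41 calibrants and 45 suspects
    across 20 reversed-phase systems with run times between 15 and 54
    minutes, about a quarter of systems using an ammonium-salt additive,
    measurement noise of 10 index units on the 0-1000 RTI scale, and
    per-system detection dropout spread widely enough that detected
    calibrant counts range from the low teens to the high thirties.
    """

    n_systems: int = 20
    n_calibrants: int = 41
    n_suspects: int = 45
    run_time_range: tuple[float, float] = (15.0, 54.0)
    frac_ionizable: float = 0.4
    additive_mix: float = 0.25
    delta_ion: float = 0.08
    noise_sd: float | None = None  # minutes; overridden by noise_rti if set
    noise_rti: float | None = 10.0  # index units on the 0-1000 scale
    dropout_rate: float = 0.25  # mean per-system dropout probability
    dropout_spread: float = 0.2  # half-width of the per-system spread
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_ionizable", "additive_mix", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def simulate_compounds(config: SimulationConfig) -> list[CompoundRecord]:
    """Draw the compound panel: latent coordinates, roles, ion classes."""
    rng = _rng(config.seed, _STREAM_COMPOUNDS)
    n = config.n_calibrants + config.n_suspects
    u = rng.uniform(0.02, 0.98, size=n)
    while np.unique(u).size < n:  # ties are measure-zero but guard anyway
        u = rng.uniform(0.02, 0.98, size=n)
    ionizable = rng.random(n) < config.frac_ionizable
    acid_or_base = rng.choice(["acid", "base"], size=n)
    pka = rng.uniform(*PKA_RANGE, size=n)
    records = []
    for i in range(n):
        role = "calibrant" if i < config.n_calibrants else "suspect"
        idx = i + 1 if role == "calibrant" else i - config.n_calibrants + 1
        records.append(CompoundRecord(
            compound_id=f"{'CAL' if role == 'calibrant' else 'SUS'}{idx:03d}",
            role=role,
            latent_u=float(u[i]),
            ion_class=acid_or_base[i] if ionizable[i] else "neutral",
            pka=float(pka[i]) if ionizable[i] else float("nan"),
        ))
    return records


def simulate_external_compounds(n: int, frac_ionizable: float,
                                seed: int) -> list[CompoundRecord]:
    """External training panel (role ``external``), disjoint from the
    study compounds by construction of the id space."""
    rng = _rng(seed, _STREAM_EXTERNAL)
    u = rng.uniform(0.02, 0.98, size=n)
    ionizable = rng.random(n) < frac_ionizable
    acid_or_base = rng.choice(["acid", "base"], size=n)
    pka = rng.uniform(*PKA_RANGE, size=n)
    return [
        CompoundRecord(
            compound_id=f"EXT{i + 1:04d}",
            role="external",
            latent_u=float(u[i]),
            ion_class=acid_or_base[i] if ionizable[i] else "neutral",
            pka=float(pka[i]) if ionizable[i] else float("nan"),
        )
        for i in range(n)
    ]


def _random_program(rng: np.random.Generator, run_time: float
                    ) -> tuple[GradientSegment, ...]:
    """Random monotone gradient program.

    Programs combine, with independent coin flips, an initial isocratic
    hold, a gradient whose speed may change at a breakpoint (optionally
    with a mid-run isocratic segment there), and a terminal plateau.
    Mid-run holds and gradient-speed changes are what make retention
    time indices nonlinearly related between systems; start offsets and
    overall scale are absorbed by the index itself.
    """
    f_hold = rng.uniform(0.03, 0.20) if rng.random() < 0.5 else 0.0
    f_plateau = rng.uniform(0.10, 0.40) if rng.random() < 0.5 else 0.0
    f_mid = rng.uniform(0.05, 0.20) if rng.random() < 0.4 else 0.0
    two_slope = rng.random() < 0.6
    phi0 = rng.uniform(0.02, 0.10)
    phi1 = rng.uniform(0.90, 0.98)

    f_grad = 1.0 - f_hold - f_plateau - f_mid
    t = 0.0
    segs = []
    if f_hold > 0:
        segs.append(GradientSegment(t, t + f_hold * run_time, phi0, phi0))
        t += f_hold * run_time
    if two_slope or f_mid > 0:
        split = rng.uniform(0.3, 0.7)
        phi_m = phi0 + rng.uniform(0.3, 0.7) * (phi1 - phi0)
        t1 = t + split * f_grad * run_time
        segs.append(GradientSegment(t, t1, phi0, phi_m))
        t = t1
        if f_mid > 0:
            segs.append(GradientSegment(t, t + f_mid * run_time,
                                        phi_m, phi_m))
            t += f_mid * run_time
        t2 = t + (1.0 - split) * f_grad * run_time
        segs.append(GradientSegment(t, t2, phi_m, phi1))
        t = t2
    else:
        segs.append(GradientSegment(t, t + f_grad * run_time, phi0, phi1))
        t += f_grad * run_time
    if f_plateau > 0:
        segs.append(GradientSegment(t, run_time, phi1, phi1))
        t = run_time
    # close any floating-point gap at the end of the program
    last = segs[-1]
    segs[-1] = GradientSegment(last.t_start, run_time, last.phi_start,
                               last.phi_end)
    return tuple(segs)


def simulate_systems(config: SimulationConfig) -> list[ChromSystem]:
    """Draw per-system metadata: run time, gradient program, additive
    class and column chemistry."""
    rng = _rng(config.seed, _STREAM_SYSTEMS)
    systems = []
    for i in range(config.n_systems):
        run_time = float(rng.uniform(*config.run_time_range))
        additive = (
            "ammonium_salt" if rng.random() < config.additive_mix
            else "formic_acid"
        )
        column = rng.choice(["C18", "C8", "biphenyl"], p=[0.6, 0.2, 0.2])
        systems.append(ChromSystem(
            cs_id=f"SIM{i + 1:02d}",
            mechanism="RP",
            column_chemistry=str(column),
            additive_class=additive,
            run_time=run_time,
            gradient_segments=_random_program(rng, run_time),
        ))
    return systems


@dataclass(frozen=True)
class Warp:
    """Strictly increasing piecewise-linear map latent_u -> RT (minutes).

    ``u_scale`` rescales the latent coordinate onto the active part of
    the elution-progress curve: with a terminal plateau (maximum organic
    fraction held), every compound has washed out shortly after the
    plateau starts, so u = 1 maps there rather than to the run end.
    """

    t_knots: np.ndarray
    g_knots: np.ndarray
    run_time: float
    dead_time: float
    u_scale: float = 1.0

    def __call__(self, u) -> np.ndarray | float:
        u = np.asarray(u, dtype=float)
        t = np.interp(u * self.u_scale, self.g_knots, self.t_knots)
        rt = self.dead_time + t * (self.run_time - self.dead_time) / \
            self.run_time
        return float(rt) if rt.ndim == 0 else rt


def build_system_warp(system: ChromSystem,
                      eta: float = ISOCRATIC_BASELINE) -> Warp:
    """Derive the elution warp from a system's gradient program.

    Elution progress g(t) combines the organic-fraction ramp with a
    small baseline drift ``eta`` that keeps elution strictly advancing
    through isocratic segments: g(t) = (1-eta) * (phi(t)-phi(0)) /
    (phi(T)-phi(0)) + eta * t/T.  The warp is the (piecewise-linear)
    inverse of g, offset by the dead time.  Isocratic plateaus therefore
    absorb little of the latent coordinate and compress elution, while
    pure linear gradients give an affine warp.
    """
    segs = system.gradient_segments
    T = system.run_time
    t_knots = [segs[0].t_start] + [s.t_end for s in segs]
    phi_knots = [segs[0].phi_start] + [s.phi_end for s in segs]
    t_knots = np.asarray(t_knots, dtype=float)
    phi_knots = np.asarray(phi_knots, dtype=float)
    span = phi_knots[-1] - phi_knots[0]
    if abs(span) < 1e-12:
        g = t_knots / T  # fully isocratic program: baseline drift only
    else:
        g = (1 - eta) * (phi_knots - phi_knots[0]) / span + \
            eta * t_knots / T
    diffs = np.diff(g)
    assert np.all(diffs > 0), (
        f"{system.cs_id}: constructed warp is not strictly increasing "
        "(gradient program must be monotone non-decreasing in organic "
        "fraction)"
    )
    dead = max(DEAD_TIME_FLOOR, 0.02 * T)
    # terminal plateau at maximum organic: elution completes in a short
    # washout just after the plateau starts, not at the run end
    u_scale = 1.0
    last = segs[-1]
    if abs(last.phi_end - last.phi_start) < 1e-12 and len(segs) > 1:
        u_scale = float(g[-2] + 0.05 * (g[-1] - g[-2]))
    return Warp(t_knots=t_knots, g_knots=g, run_time=T, dead_time=dead,
                u_scale=u_scale)


@dataclass
class StudyTruth:
    """Ground truth retained for oracle checks."""

    compounds: list[CompoundRecord]
    warps: dict[str, Warp]
    u_effective: pd.DataFrame  # compounds x systems latent coordinates
    noise_sd_minutes: dict[str, float]
    dropout_p: dict[str, float]


def simulate_study(config: SimulationConfig
                   ) -> tuple[RetentionTable, list[ChromSystem], StudyTruth]:
    """Generate the full synthetic interlaboratory study."""
    compounds = simulate_compounds(config)
    systems = simulate_systems(config)
    noise_rng = _rng(config.seed, _STREAM_NOISE)
    drop_rng = _rng(config.seed, _STREAM_DROPOUT)

    ids = [c.compound_id for c in compounds]
    u = np.array([c.latent_u for c in compounds])
    sign = np.array([c.ion_sign for c in compounds], dtype=float)

    rt = pd.DataFrame(index=pd.Index(ids, name="compound_id"))
    u_eff_all = pd.DataFrame(index=rt.index)
    warps, noise_map, drop_map = {}, {}, {}
    for sysrec in systems:
        warp = build_system_warp(sysrec)
        warps[sysrec.cs_id] = warp
        u_eff = u.copy()
        if sysrec.additive_class == "ammonium_salt":
            u_eff = np.clip(u + config.delta_ion * sign, 0.005, 0.995)
        rts = np.asarray(warp(u_eff), dtype=float)
        if config.noise_rti is not None:
            span = float(warp(0.98) - warp(0.02))
            sd = config.noise_rti / 1000.0 * span
        else:
            sd = float(config.noise_sd or 0.0)
        if sd > 0:
            rts = rts + noise_rng.normal(0.0, sd, size=rts.size)
        rts = np.clip(rts, 0.05, sysrec.run_time)
        if config.dropout_rate > 0:
            p = float(np.clip(
                drop_rng.uniform(config.dropout_rate - config.dropout_spread,
                                 config.dropout_rate + config.dropout_spread),
                0.0, 0.95,
            ))
            detected = drop_rng.random(rts.size) >= p
            rts = np.where(detected, rts, np.nan)
        else:
            p = 0.0
        rt[sysrec.cs_id] = rts
        u_eff_all[sysrec.cs_id] = u_eff
        noise_map[sysrec.cs_id] = sd
        drop_map[sysrec.cs_id] = p

    meta = pd.DataFrame(
        {
            "role": [c.role for c in compounds],
            "smiles": "",
            "inchikey": "",
        },
        index=rt.index,
    )
    table = RetentionTable(meta, rt)
    truth = StudyTruth(
        compounds=compounds,
        warps=warps,
        u_effective=u_eff_all,
        noise_sd_minutes=noise_map,
        dropout_p=drop_map,
    )
    return table, systems, truth


# descriptor feature shapes: monotone transforms of the latent coordinate
_FEATURE_FUNCS = (
    lambda u: u,
    lambda u: u**2,
    lambda u: np.sqrt(u),
    lambda u: np.log(u + 0.1),
    lambda u: 1.0 / (1.0 + np.exp(-6.0 * (u - 0.5))),
)


def simulate_descriptors(compounds: list[CompoundRecord],
                         n_descriptors: int = 60,
                         n_informative: int = 5,
                         noise_sd: float = 0.05,
                         seed: int = 0,
                         include_ion_column: bool = True,
                         n_constant: int = 0,
                         n_duplicate: int = 0,
                         n_missing_polluted: int = 0,
                         missing_count: int = 20) -> DescriptorMatrix:
    """Synthetic descriptor matrix standing in for computed molecular
    descriptors.

    Informative columns are noisy monotone transforms of the latent
    elution coordinate; when ``include_ion_column`` is set one of them
    encodes acid/base character (the structural handle through which a
    model can learn additive-dependent retention shifts).  Remaining
    columns are pure noise.  Optional planted defects (constant,
    duplicated and missing-polluted columns) exercise the cleaning
    rules.
    """
    if n_informative > n_descriptors:
        raise ValueError("n_informative cannot exceed n_descriptors")
    rng = _rng(seed, _STREAM_DESCRIPTORS)
    ids = [c.compound_id for c in compounds]
    u = np.array([c.latent_u for c in compounds])
    sign = np.array([c.ion_sign for c in compounds], dtype=float)
    n = len(ids)

    cols, names = [], []
    n_u_informative = n_informative - (1 if include_ion_column else 0)
    for j in range(n_u_informative):
        f = _FEATURE_FUNCS[j % len(_FEATURE_FUNCS)]
        scale = rng.uniform(0.5, 2.0)
        cols.append(scale * f(u) + rng.normal(0, noise_sd, n))
        names.append(f"info_{j + 1:02d}")
    if include_ion_column:
        cols.append(sign + rng.normal(0, noise_sd, n))
        names.append("ion_character")
    for j in range(n_descriptors - n_informative):
        cols.append(rng.normal(0, 1, n))
        names.append(f"noise_{j + 1:03d}")
    for j in range(n_constant):
        cols.append(np.full(n, 3.14))
        names.append(f"const_{j + 1:02d}")
    for j in range(n_duplicate):
        cols.append(cols[j % max(1, n_informative)].copy())
        names.append(f"dup_{j + 1:02d}")
    for j in range(n_missing_polluted):
        col = rng.normal(0, 1, n)
        miss_idx = rng.choice(n, size=min(missing_count, n), replace=False)
        col[miss_idx] = np.nan
        cols.append(col)
        names.append(f"miss_{j + 1:02d}")

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(ids, name="compound_id"),
        columns=names,
    )
    return DescriptorMatrix(values=values, cleaning_log={})


def study_to_config(config: SimulationConfig, **overrides
                    ) -> SimulationConfig:
    """Convenience: derive a modified copy of a config."""
    return replace(config, **overrides)
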