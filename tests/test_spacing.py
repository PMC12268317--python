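import numpy as np
import pytest

from rtbridge.errors import InsufficientDataError, ValidationError
from rtbridge.io import ChromSystem, GradientSegment
from rtbridge.simulate import build_system_warp, simulate_compounds, \
    SimulationConfig
from rtbridge.spacing import normalize_rts, spacing_summary

from conftest import linear_system, make_table


@pytest.mark.parametrize("rt,expected", [(10.0, 500.0), (20.0, 1000.0)])
def test_normalize_rts_values(rt, expected):
    assert normalize_rts(rt, 20.0) == pytest.approx(expected)


def test_normalize_rts_rejects_rt_beyond_program():
    with pytest.raises(ValidationError):
        normalize_rts(21.0, 20.0)


def test_normalization_is_scale_free():
    rts = np.array([1.0, 5.0, 9.0])
    assert np.allclose(normalize_rts(rts, 10.0), normalize_rts(2 * rts, 20.0))


def test_spacing_summary_uniform_staircase():
    # normalized RTs (essentially) 0,250,500,750,1000 on the index scale
    grid = np.linspace(1e-3, 20.0, 5)
    roles = {f"X{i}": "suspect" for i in range(5)}
    rts = {"A": {f"X{i}": grid[i] for i in range(5)},
           "B": {f"X{i}": 1.0 + i for i in range(5)}}
    table = make_table(rts, roles)
    summ = spacing_summary(table, linear_system("A", run_time=20.0))
    assert np.allclose(summ.normalized_rts,
                       [0.0, 250.0, 500.0, 750.0, 1000.0], atol=0.1)
    # sample sd of the uniform staircase: sqrt(156250) = 395.28...
    assert summ.sd_normalized == pytest.approx(395.28, abs=0.2)
    assert np.allclose(summ.cumulative_curve["fraction"],
                       [0.2, 0.4, 0.6, 0.8, 1.0])


def test_spacing_summary_degenerate_single_rt():
    roles = {"X0": "suspect", "X1": "suspect"}
    rts = {"A": {"X0": 5.0, "X1": 5.0}, "B": {"X0": 1.0, "X1": 2.0}}
    summ = spacing_summary(make_table(rts, roles),
                           linear_system("A", run_time=20.0))
    assert summ.sd_normalized == 0.0


def test_spacing_summary_needs_two_detections():
    roles = {"X0": "suspect", "X1": "suspect"}
    rts = {"A": {"X0": 5.0}, "B": {"X0": 1.0, "X1": 2.0}}
    with pytest.raises(InsufficientDataError):
        spacing_summary(make_table(rts, roles), linear_system("A", 20.0))


def _warp_system(cs_id, run_time, segments):
    return ChromSystem(cs_id, "RP", "C18", "formic_acid", run_time,
                       tuple(GradientSegment(*s) for s in segments))


def test_terminal_plateau_compresses_late_eluters():
    """A long terminal isocratic plateau washes everything out early:
    the largest normalized RT stays low, while a pure gradient spreads
    elution over nearly the whole program (20-seed medians)."""
    T = 30.0
    pure = _warp_system("P", T, [(0, T, 0.05, 0.95)])
    plateau = _warp_system("Q", T, [(0, 0.6 * T, 0.05, 0.95),
                                    (0.6 * T, T, 0.95, 0.95)])
    max_pure, max_plat = [], []
    for seed in range(20):
        cpds = simulate_compounds(SimulationConfig(seed=seed))
        u = np.array([c.latent_u for c in cpds])
        max_pure.append(1000 * np.max(build_system_warp(pure)(u)) / T)
        max_plat.append(1000 * np.max(build_system_warp(plateau)(u)) / T)
    assert np.median(max_plat) < 700
    assert np.median(max_pure) > 950


def test_longer_gradient_share_spreads_peaks():
    """Programs spending >50% of run time in the gradient yield a larger
    spread of normalized RTs than programs with <40% gradient."""
    T = 40.0
    wide = _warp_system("W", T, [(0, 0.1 * T, 0.05, 0.05),
                                 (0.1 * T, 0.8 * T, 0.05, 0.95),
                                 (0.8 * T, T, 0.95, 0.95)])  # 70% gradient
    narrow = _warp_system("N", T, [(0, 0.35 * T, 0.05, 0.05),
                                   (0.35 * T, 0.65 * T, 0.05, 0.95),
                                   (0.65 * T, T, 0.95, 0.95)])  # 30%
    sd_wide, sd_narrow = [], []
    for seed in range(20):
        cpds = simulate_compounds(SimulationConfig(seed=seed))
        u = np.array([c.latent_u for c in cpds])
        roles = {c.compound_id: c.role for c in cpds}
        rts = {
            "W": dict(zip(roles, build_system_warp(wide)(u))),
            "N": dict(zip(roles, build_system_warp(narrow)(u))),
        }
        table = make_table(rts, roles)
        sd_wide.append(spacing_summary(table, wide).sd_normalized)
        sd_narrow.append(spacing_summary(table, narrow).sd_normalized)
    assert np.median(sd_wide) > np.median(sd_narrow)
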