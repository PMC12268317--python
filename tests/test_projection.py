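import dataclasses

import numpy as np
import pandas as pd
import pytest

from rtbridge.errors import DegenerateFitError, InsufficientAnchorsError
from rtbridge.gam import fit_penalized_spline
from rtbridge.projection import (fit_projection_gam, project_pair,
                                 project_rti, run_all_pairs)
from rtbridge.rti import PairRTIData
from rtbridge.simulate import SimulationConfig, simulate_study


def _pair_from_xy(x, y, suspects_x=None, suspects_y=None) -> PairRTIData:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cal = pd.DataFrame({
        "compound_id": [f"C{i}" for i in range(x.size)],
        "rti_source": x, "rti_target": y,
    })
    if suspects_x is None:
        suspects_x = np.array([])
        suspects_y = np.array([])
    suspects_x = np.asarray(suspects_x, dtype=float)
    suspects_y = np.asarray(suspects_y, dtype=float)
    sus = pd.DataFrame({
        "compound_id": [f"S{i}" for i in range(suspects_x.size)],
        "rti_source": suspects_x, "rti_target": suspects_y,
        "in_range_source": (suspects_x >= 0) & (suspects_x <= 1000),
        "in_range_target": (suspects_y >= 0) & (suspects_y <= 1000),
    })
    return PairRTIData(
        cs_source="A", cs_target="B",
        shared_calibrant_ids=list(cal["compound_id"]),
        anchors_source=(0.0, 1.0), anchors_target=(0.0, 1.0),
        calibrants=cal, suspects=sus,
    )


def test_identity_pair_projects_identically():
    x = np.linspace(0, 1000, 20)
    pair = _pair_from_xy(x, x)
    model = fit_projection_gam(pair)
    grid = np.array([0.0, 137.5, 500.0, 862.5, 1000.0])
    assert np.allclose(project_rti(model, grid)["rti_projected"], grid,
                       atol=1.0)


def test_noise_free_cubic_warp_recovered():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0, 1000, 30))
    warp = lambda t: 1000 * (0.3 * (t / 1000) + 0.7 * (t / 1000) ** 3)
    sx = rng.uniform(0, 1000, 25)
    pair = _pair_from_xy(x, warp(x), sx, warp(sx))
    res = project_pair(pair)
    assert res.error_summary_post_gam.rmse < 5.0


def test_min_shared_calibrants_enforced():
    x = np.linspace(0, 1000, 5)
    with pytest.raises(InsufficientAnchorsError):
        fit_projection_gam(_pair_from_xy(x, x), min_shared=8)


def test_degenerate_all_equal_sources():
    x = np.full(12, 500.0)
    with pytest.raises(DegenerateFitError):
        fit_penalized_spline(x, x, bounds=(0.0, 1000.0))


def test_out_of_range_sources_excluded_boundaries_kept():
    x = np.linspace(0, 1000, 20)
    model = fit_projection_gam(_pair_from_xy(x, x))
    out = project_rti(model, [1100.0, -5.0, 0.0, 1000.0, np.nan])
    assert list(out["exclusion_reason"]) == [
        "out_of_range", "out_of_range", "", "", "undetected"
    ]
    assert np.isfinite(out["rti_projected"][2:4]).all()


def test_gam_fit_is_direction_asymmetric():
    """The smooth minimizes residuals toward the target axis, so the two
    directions are separate fits that may disagree in accuracy."""
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(0, 1000, 25))
    y = 1000 * (x / 1000) ** 2 + rng.normal(0, 15, x.size)
    y = np.clip(y, 0, 1000)
    fwd = fit_projection_gam(_pair_from_xy(x, y))
    rev = fit_projection_gam(_pair_from_xy(y, x))
    grid = np.linspace(0, 1000, 11)
    back = rev.spline.predict(np.clip(fwd.spline.predict(grid), 0, 1000))
    assert not np.allclose(back, grid, atol=1.0)  # not mutual inverses


def test_run_all_pairs_counts_ordered_pairs():
    cfg = SimulationConfig(n_systems=5, seed=2, dropout_rate=0.0)
    table, systems, _ = simulate_study(cfg)
    results, skipped = run_all_pairs(table, systems)
    assert len(results) + len(skipped) == 20  # n(n-1)


def test_duplicate_systems_reach_noise_floor():
    """Projecting between two noisy copies of the same system leaves
    only measurement noise: post-GAM RMSE <= 2 sigma."""
    cfg = SimulationConfig(n_systems=2, seed=4, dropout_rate=0.0,
                           additive_mix=0.0, noise_rti=10.0)
    table, systems, truth = simulate_study(cfg)
    # overwrite the second system with an independently noisy copy of
    # the first: same warp, fresh noise
    warp = truth.warps["SIM01"]
    u = np.array([c.latent_u for c in truth.compounds])
    rng = np.random.default_rng(99)
    span = warp(0.98) - warp(0.02)
    rt = table.rt.copy()
    rt["SIM02"] = np.asarray(warp(u)) + rng.normal(0, 10 / 1000 * span,
                                                   u.size)
    table = dataclasses.replace(table, rt=rt)
    results, _ = run_all_pairs(table, [systems[0],
                                       dataclasses.replace(
                                           systems[1],
                                           run_time=systems[0].run_time,
                                           gradient_segments=systems[0]
                                           .gradient_segments)])
    for r in results:
        assert r.error_summary_post_gam.rmse <= 2 * 10.0


def test_non_rp_systems_excluded_from_pairs():
    cfg = SimulationConfig(n_systems=4, seed=6, dropout_rate=0.0)
    table, systems, _ = simulate_study(cfg)
    systems[0] = dataclasses.replace(systems[0], mechanism="mixed")
    results, skipped = run_all_pairs(table, systems)
    involved = {r.cs_source for r in results} | {r.cs_target for r in results}
    assert systems[0].cs_id not in involved
    assert len(results) + len(skipped) == 6  # 3 RP systems only
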