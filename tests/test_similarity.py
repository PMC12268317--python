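import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtbridge.errors import InsufficientOverlapError
from rtbridge.similarity import (cluster_order, pairwise_correlation,
                                 similarity_matrix)
from rtbridge.simulate import SimulationConfig, simulate_study

from conftest import make_table


def test_affine_relation_gives_unit_correlation():
    a = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
    b = 2 * a + 1
    assert pairwise_correlation(a, b, "pearson") == pytest.approx(1.0)
    assert pairwise_correlation(a, b, "spearman") == pytest.approx(1.0)


def test_monotone_nonlinear_relation_separates_methods():
    a = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
    b = np.exp(a)
    assert pairwise_correlation(a, b, "spearman") == pytest.approx(1.0)
    assert pairwise_correlation(a, b, "pearson") < 1.0


def test_spearman_matches_rank_difference_formula():
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,0,0): 1 - 12/60 = 0.8
    assert pairwise_correlation(
        [1, 2, 3, 4], [2, 1, 3, 4], "spearman"
    ) == pytest.approx(0.8)


def test_correlation_error_cases():
    with pytest.raises(InsufficientOverlapError):
        pairwise_correlation([1, 2], [3, 4])
    with pytest.raises(InsufficientOverlapError):
        pairwise_correlation([1, 2, 3], [5, 5, 5])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_spearman_invariant_under_random_monotone_warp(seed):
    """Any strictly increasing transform of one system's RTs leaves the
    rank correlation untouched."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(1, 30, 12)
    b = rng.uniform(1, 30, 12)
    base = pairwise_correlation(a, b, "spearman")
    # random strictly increasing piecewise-linear warp applied to b
    slopes = rng.uniform(0.1, 5.0, b.size)
    order = np.argsort(b)
    warped = np.empty_like(b)
    warped[order] = np.cumsum(slopes)
    assert pairwise_correlation(a, warped, "spearman") == pytest.approx(base)


def test_similarity_matrix_symmetric_unit_diagonal(small_study):
    _, table, _, _ = small_study
    mat = similarity_matrix(table, "spearman")
    vals = mat.values.to_numpy()
    assert np.allclose(vals, vals.T, equal_nan=True)
    assert np.allclose(np.diag(vals), 1.0)
    finite = vals[np.isfinite(vals)]
    assert ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all()


def test_duplicate_system_has_unit_offdiagonal():
    roles = {f"X{i}": "calibrant" for i in range(5)}
    rts = {"A": {f"X{i}": 1.0 + i for i in range(5)}}
    rts["B"] = dict(rts["A"])  # identical duplicate
    rts["C"] = {f"X{i}": 1.0 + 2 * i + (i == 2) * 3 for i in range(5)}
    mat = similarity_matrix(make_table(rts, roles), "pearson")
    assert mat.values.loc["A", "B"] == pytest.approx(1.0)


def test_reversed_gradient_system_anticorrelates():
    cfg = SimulationConfig(n_systems=4, seed=3, noise_rti=None,
                           noise_sd=0.0, dropout_rate=0.0, additive_mix=0.0)
    table, _, _ = simulate_study(cfg)
    rev = table.rt.copy()
    rev["REV"] = rev["SIM01"].max() + rev["SIM01"].min() - rev["SIM01"]
    table = dataclasses.replace(table, rt=rev)
    mat = similarity_matrix(table, "spearman")
    others = [c for c in mat.cs_ids if c != "REV"]
    assert (mat.values.loc["REV", others] < 0).all()


def test_cluster_order_merges_duplicates_first():
    roles = {f"X{i}": "calibrant" for i in range(6)}
    rng = np.random.default_rng(0)
    base = {f"X{i}": v for i, v in enumerate(rng.uniform(1, 20, 6))}
    rts = {"A": base, "B": dict(base)}
    for cs in ("C", "D", "E"):
        rts[cs] = {k: v for k, v in
                   zip(base, rng.permutation(list(base.values())))}
    order, link = cluster_order(similarity_matrix(make_table(rts, roles),
                                                  "spearman"))
    # zero-distance duplicates are the first merge, hence adjacent leaves
    assert abs(order.index("A") - order.index("B")) == 1
    assert link[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_cluster_order_degenerate_identity_matrix_is_lexical():
    roles = {f"X{i}": "calibrant" for i in range(4)}
    base = {f"X{i}": 1.0 + i for i in range(4)}
    rts = {cs: dict(base) for cs in ("b", "a", "d", "c")}
    order, _ = cluster_order(similarity_matrix(make_table(rts, roles),
                                               "spearman"))
    assert sorted(order) == ["a", "b", "c", "d"]
    assert order == sorted(order)  # deterministic lexical tie-break


def test_basic_compounds_rank_later_under_ammonium_additive():
    """On buffered (higher-pH) systems bases are retained longer, so
    their within-system rank is strictly higher than on acidic systems."""
    cfg = SimulationConfig(n_systems=6, additive_mix=0.5, seed=5,
                           noise_rti=None, noise_sd=0.0, dropout_rate=0.0)
    table, systems, truth = simulate_study(cfg)
    bases = [c.compound_id for c in truth.compounds
             if c.ion_class == "base"]
    assert bases
    amm = [s.cs_id for s in systems if s.additive_class == "ammonium_salt"]
    frm = [s.cs_id for s in systems if s.additive_class == "formic_acid"]
    assert amm and frm
    ranks = table.rt.rank()
    for b in bases:
        assert ranks.loc[b, amm].min() >= ranks.loc[b, frm].max()
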