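"""End-to-end orchestration of the comparability analysis.

Stages: ingest or simulate -> RTI -> similarity -> peak spacing ->
pair projection -> retention prediction -> projection-vs-prediction
comparison -> report bundle.  All tabular outputs are deterministic
CSV/JSON; a manifest records versions, configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import (aggregate_comparison, classify_pair, fraction_improved)
from .errors import InsufficientAnchorsError, RTBridgeError
from .io import (ChromSystem, GradientSegment, RetentionTable,
                 read_cs_metadata, read_rt_table, write_cs_metadata,
                 write_rt_table, write_table)
from .prediction import (DEFAULT_GRID, FAST_GRID, clean_descriptor_matrix,
                         predict_and_calibrate, train_local_model,
                         train_rt_model)
from .projection import run_all_pairs
from .rti import system_rti
from .similarity import cluster_order, similarity_matrix
from .simulate import (SimulationConfig, _STREAM_TRAINING_NOISE, _rng,
                       build_system_warp, simulate_descriptors,
                       simulate_external_compounds, simulate_study)
from .spacing import spacing_summary

logger = logging.getLogger(__name__)


def make_training_system(additive_class: str = "ammonium_salt"
                         ) -> ChromSystem:
    """The chromatographic system behind the external training table: a
    short buffered-mobile-phase program with a single linear gradient."""
    return ChromSystem(
        cs_id="TRAIN",
        mechanism="RP",
        column_chemistry="C18",
        additive_class=additive_class,
        run_time=15.5,
        gradient_segments=(
            GradientSegment(0.0, 1.0, 0.05, 0.05),
            GradientSegment(1.0, 13.0, 0.05, 0.95),
            GradientSegment(13.0, 15.5, 0.95, 0.95),
        ),
    )


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    simulation: SimulationConfig | None = None
    compounds_path: str | None = None
    systems_path: str | None = None
    min_shared: int = 8
    alpha: float = 0.05
    k: int = 6
    include_out_of_range_targets: bool = True
    linear_calibration_variant: bool = False
    mechanism_filter: str = "RP_only"
    # prediction arm
    run_prediction: bool = True
    synthetic_descriptors: bool = True
    n_external_training: int = 300
    training_additive: str = "ammonium_salt"
    fast_prediction_grid: bool = False
    include_local_models: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.simulation is None and (
            self.compounds_path is None or self.systems_path is None
        ):
            raise ValueError(
                "either a SimulationConfig or input paths are required"
            )

    @property
    def seed(self) -> int:
        return self.simulation.seed if self.simulation is not None else 0


def _plot_heatmap(matrix, order, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = matrix.values.loc[order, order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(vals.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{matrix.method} coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_spacing(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for cs_id, grp in curves.groupby("cs_id"):
        ax.step(grp["normalized_rt"], grp["fraction"], where="post",
                lw=0.8, alpha=0.7)
    ax.set_xlabel("normalized RT (index units)")
    ax.set_ylabel("fraction of compounds eluted")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns a summary dict with the key aggregates and output paths.
    On stage failure, outputs written so far are preserved and the
    exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"outputs": {}}

    def _out(name: str) -> Path:
        p = outdir / name
        summary["outputs"][name.split(".")[0]] = str(p)
        return p

    # -- stage 1: data ----------------------------------------------------
    truth = None
    if config.simulation is not None:
        table, systems, truth = simulate_study(config.simulation)
        write_rt_table(table, _out("compounds.csv"))
        write_cs_metadata(systems, _out("systems.csv"))
    else:
        table = read_rt_table(config.compounds_path)
        systems = read_cs_metadata(config.systems_path)
    logger.info("stage data: %d compounds x %d systems (%.1fs)",
                len(table.compound_ids), len(table.system_ids),
                time.time() - t0)

    if config.mechanism_filter == "RP_only":
        rp = [s for s in systems if s.mechanism == "RP"]
        if len(rp) < len(systems):
            logger.info("excluded %d non-RP systems", len(systems) - len(rp))
        systems = rp
        table = table.subset_systems([s.cs_id for s in systems])
    sysmap = {s.cs_id: s for s in systems}

    # -- stage 2: similarity + clustering ---------------------------------
    t = time.time()
    sim_records = []
    for method in ("pearson", "spearman"):
        mat = similarity_matrix(table, method=method)
        long = mat.values.stack().rename("coefficient").reset_index()
        long.columns = ["cs_a", "cs_b", "coefficient"]
        long["method"] = method
        long["n_shared"] = [
            mat.n_shared.loc[a, b] for a, b in zip(long.cs_a, long.cs_b)
        ]
        sim_records.append(long)
        if method == "spearman":
            order, _ = cluster_order(mat)
            _out("cluster_order.txt").write_text("\n".join(order) + "\n")
            _plot_heatmap(mat, order, _out("heatmap.png"))
            summary["cluster_order"] = order
    write_table(pd.concat(sim_records, ignore_index=True),
                _out("similarity.csv"), keys=["method", "cs_a", "cs_b"])
    logger.info("stage similarity (%.1fs)", time.time() - t)

    # -- stage 3: peak spacing --------------------------------------------
    t = time.time()
    spacing_rows, curve_rows = [], []
    for s in systems:
        try:
            summ = spacing_summary(table, s)
        except RTBridgeError as exc:
            logger.warning("spacing %s: %s", s.cs_id, exc)
            continue
        spacing_rows.append({
            "cs_id": s.cs_id,
            "n_detected": summ.n_detected,
            "sd_normalized": summ.sd_normalized,
            "max_normalized": summ.max_normalized,
            "gradient_fraction": s.gradient_fraction,
        })
        c = summ.cumulative_curve.copy()
        c.insert(0, "cs_id", s.cs_id)
        curve_rows.append(c)
    write_table(spacing_rows, _out("spacing_summary.csv"), keys=["cs_id"])
    curves = pd.concat(curve_rows, ignore_index=True)
    write_table(curves, _out("spacing_curves.csv"),
                keys=["cs_id", "normalized_rt"])
    _plot_spacing(curves, _out("spacing_cdf.png"))
    logger.info("stage spacing (%.1fs)", time.time() - t)

    # -- stage 4: pair projection -----------------------------------------
    t = time.time()
    results, skipped = run_all_pairs(
        table, systems, k=config.k, min_shared=config.min_shared,
        include_out_of_range_targets=config.include_out_of_range_targets,
    )
    pair_rows = [r.to_record() for r in results]
    write_table(pair_rows, _out("projection_pairs.csv"),
                keys=["cs_source", "cs_target"])
    detail = []
    for r in results:
        d = r.suspects.copy()
        d.insert(0, "cs_source", r.cs_source)
        d.insert(1, "cs_target", r.cs_target)
        detail.append(d)
    write_table(pd.concat(detail, ignore_index=True),
                _out("projection_detail.csv"),
                keys=["cs_source", "cs_target", "compound_id"])
    skip_frame = pd.DataFrame(
        skipped, columns=["cs_source", "cs_target", "reason"]
    )
    if len(skip_frame):
        write_table(skip_frame, _out("projection_skipped.csv"),
                    keys=["cs_source", "cs_target"])
    pair_frame = pd.DataFrame(pair_rows)
    summary["n_pairs_projected"] = len(results)
    summary["n_pairs_skipped"] = len(skipped)
    summary["fraction_improved_post_gam"] = fraction_improved(
        pair_frame["pre_rmse"], pair_frame["post_rmse"]
    )
    logger.info("stage projection: %d pairs (%.1fs)", len(results),
                time.time() - t)

    # -- stage 5: prediction arm ------------------------------------------
    pred_residuals: dict[str, dict] = {}
    if config.run_prediction and (
        config.synthetic_descriptors and config.simulation is not None
    ):
        t = time.time()
        sim = config.simulation
        ext = simulate_external_compounds(
            config.n_external_training, sim.frac_ionizable, sim.seed
        )
        study_cpds = truth.compounds
        ext_ids = {c.compound_id for c in ext}
        assert ext_ids.isdisjoint(c.compound_id for c in study_cpds)
        dm_all = simulate_descriptors(
            ext + study_cpds, seed=sim.seed,
            n_constant=1, n_duplicate=1, n_missing_polluted=1,
        )
        cleaned = clean_descriptor_matrix(dm_all)

        tsys = make_training_system(config.training_additive)
        warp = build_system_warp(tsys)
        sign = np.array([c.ion_sign for c in ext], dtype=float)
        u = np.array([c.latent_u for c in ext])
        if tsys.additive_class == "ammonium_salt":
            u = np.clip(u + sim.delta_ion * sign, 0.005, 0.995)
        rng = _rng(sim.seed, _STREAM_TRAINING_NOISE)
        span = float(warp(0.98) - warp(0.02))
        sd = (sim.noise_rti or 0.0) / 1000.0 * span
        rt_ext = np.asarray(warp(u)) + rng.normal(0.0, sd, len(ext))

        ext_keep = [c for c in cleaned.compound_ids if c in ext_ids]
        rt_map = dict(zip((c.compound_id for c in ext), rt_ext))
        model = train_rt_model(
            cleaned.subset(ext_keep),
            [rt_map[c] for c in ext_keep],
            seed=sim.seed,
            param_grid=FAST_GRID if config.fast_prediction_grid
            else DEFAULT_GRID,
        )

        pred_rows, pred_detail = [], []
        for s in systems:
            try:
                rti_obs = system_rti(table, s.cs_id)
            except RTBridgeError as exc:
                logger.warning("prediction %s: %s", s.cs_id, exc)
                continue
            cal_ids = [c for c in table.calibrant_ids
                       if c in rti_obs.index and c in cleaned.compound_ids]
            sus_ids = [c for c in table.suspect_ids
                       if c in rti_obs.index and c in cleaned.compound_ids]
            if len(cal_ids) < config.min_shared or not sus_ids:
                continue
            try:
                calib = predict_and_calibrate(
                    model,
                    cleaned.subset(sus_ids),
                    cleaned.subset(cal_ids),
                    rti_obs[cal_ids].to_numpy(),
                    k=config.k, min_shared=config.min_shared,
                    linear=config.linear_calibration_variant,
                )
            except RTBridgeError as exc:
                logger.warning("prediction %s: %s", s.cs_id, exc)
                continue
            sus_pred = calib.suspect_rti()
            resid = {
                cid: float(sus_pred[cid] - rti_obs[cid])
                for cid in sus_pred.index
            }
            pred_residuals[s.cs_id] = resid
            cal_res = (calib.calibrants["rti_fitted"]
                       - calib.calibrants["rti_observed"]).to_numpy()
            sus_res = np.array(list(resid.values()))
            row = {
                "cs_id": s.cs_id,
                "additive_class": s.additive_class,
                "n_calibrants": len(cal_ids),
                "n_suspects": len(resid),
                "cal_rmse": float(np.sqrt(np.mean(cal_res**2))),
                "sus_rmse": float(np.sqrt(np.mean(sus_res**2)))
                if len(sus_res) else np.nan,
                "sus_mad": float(np.mean(np.abs(sus_res)))
                if len(sus_res) else np.nan,
                "sus_p95": float(np.percentile(np.abs(sus_res), 95))
                if len(sus_res) else np.nan,
            }
            if config.include_local_models and len(cal_ids) >= 10:
                local = train_local_model(
                    cleaned.subset(cal_ids), rti_obs[cal_ids].to_numpy(),
                    seed=sim.seed,
                )
                lp = local.predict(cleaned.subset(sus_ids))
                lres = lp - rti_obs[sus_ids].to_numpy()
                row["local_rmse"] = float(np.sqrt(np.mean(lres**2)))
            pred_rows.append(row)
            d = calib.suspects.copy()
            d.insert(0, "cs_id", s.cs_id)
            d["rti_observed"] = [rti_obs.get(c, np.nan)
                                 for c in d["compound_id"]]
            pred_detail.append(d)
        if pred_rows:
            write_table(pred_rows, _out("prediction_summary.csv"),
                        keys=["cs_id"])
            write_table(pd.concat(pred_detail, ignore_index=True),
                        _out("prediction_detail.csv"),
                        keys=["cs_id", "compound_id"])
            all_res = np.concatenate(
                [np.array(list(r.values())) for r in pred_residuals.values()]
            )
            summary["prediction_rmse_overall"] = float(
                np.sqrt(np.mean(all_res**2))
            )
        logger.info("stage prediction: %d systems (%.1fs)", len(pred_rows),
                    time.time() - t)
    elif config.run_prediction:
        logger.info("prediction arm skipped: no training data and no "
                    "synthetic-descriptor source")

    # -- stage 6: projection vs prediction --------------------------------
    if pred_residuals:
        t = time.time()
        records = []
        for r in results:
            if r.cs_target not in pred_residuals:
                continue
            records.append(classify_pair(
                r.cs_source, r.cs_target,
                r.suspect_residuals(), pred_residuals[r.cs_target],
                alpha=config.alpha,
            ))
        write_table([r.to_record() for r in records],
                    _out("comparison_pairs.csv"),
                    keys=["cs_source", "cs_target"])
        agg = aggregate_comparison(records)
        agg["fraction_improved_post_gam"] = summary[
            "fraction_improved_post_gam"
        ]
        with open(_out("comparison_summary.json"), "w") as fh:
            json.dump(agg, fh, indent=2, sort_keys=True)
        summary["comparison"] = agg
        logger.info("stage comparison: %d pairs (%.1fs)", len(records),
                    time.time() - t)

    manifest = {
        "rtbridge_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
    }
    with open(_out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete (%.1fs total)", time.time() - t0)
    return summary
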