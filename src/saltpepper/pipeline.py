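"""End-to-end runner: simulate (optional) -> preprocess -> fit -> select
-> cluster, with all intermediates persisted and a JSON run report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, clustering, io
from .config import PipelineConfig
from .kernel_fit import FitConfig, _CellDesign, fit_cell, select_cells
from .preprocess import CalciumModel, TraceSet, preprocess_traces
from .stimulus import ScreenGeometry, StimulusSequence, build_design
from .synthetic_data import ResponseConfig, SheetConfig, generate_dataset

log = logging.getLogger("saltpepper")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Summary of one pipeline run; every number traces to a stage output."""

    version: str
    config_hash: str
    seed: int
    n_cells: int = 0
    n_frames: int = 0
    n_significant: int = 0
    field_accepted: bool = False
    n_pairs: int = 0
    lambda_um: float | None = None
    lambda_ci95_um: tuple[float, float] | None = None
    lambda_identifiable: bool | None = None
    asymptote: float | None = None
    amplitude: float | None = None
    first_bin_p: float | None = None
    near_far_ori_p: float | None = None
    near_far_sf_p: float | None = None
    field_correlation_r: float | None = None
    field_correlation_p: float | None = None
    filter_first_bin_p: dict = field(default_factory=dict)
    depth_first_bin_p: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _fit_config(config: PipelineConfig) -> FitConfig:
    f = config.fit
    return FitConfig(
        n_lags=f.n_lags, penalty_grid=tuple(f.penalty_grid), n_folds=f.n_folds,
        max_als_iters=f.max_als_iters, tol=f.tol,
        r_L_threshold=f.r_L_threshold, seed=config.seed,
    )


def cluster_cells(
    kernels: np.ndarray,
    positions: np.ndarray,
    cells_table,
    config: PipelineConfig,
    seed: int,
    report: RunReport,
    out_dir=None,
) -> None:
    """Run the clustering stage and record its statistics in the report."""
    cl = config.clustering
    edges = cl.bin_edges_um
    pt = clustering.build_pair_table(
        kernels, positions,
        pref_orientation_deg=cells_table["pref_orientation_deg"].to_numpy(),
        pref_sf_cpd=cells_table["pref_sf_cpd"].to_numpy(),
    )
    report.n_pairs = len(pt)
    curve = clustering.bin_similarity(pt, edges)
    report.first_bin_p = float(curve.ranksum_p_vs_last[0])
    fit = clustering.fit_exponential_decay(pt, edges, n_boot=cl.n_boot, seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        pt.to_csv(out_dir / "pairs.csv")
        curve.to_frame().to_csv(out_dir / "similarity_curve.csv", index=False)
        from .plotting import plot_similarity_curve

        ax = plot_similarity_curve(curve, fit, out_dir / "similarity_curve.png")
        import matplotlib.pyplot as plt

        plt.close(ax.figure)
    report.lambda_um = fit.length_constant_um
    report.lambda_ci95_um = fit.ci95_lambda_um
    report.lambda_identifiable = fit.identifiable
    report.asymptote = fit.asymptote
    report.amplitude = fit.amplitude
    try:
        report.near_far_ori_p = clustering.near_far_preference_test(
            pt, cl.near_um, cl.far_um, "d_ori_deg")
        report.near_far_sf_p = clustering.near_far_preference_test(
            pt, cl.near_um, cl.far_um, "d_log_sf")
    except ValueError as e:
        report.notes.append(f"near/far test skipped: {e}")
    try:
        r, p = clustering.per_field_correlation(pt)
        report.field_correlation_r = r
        report.field_correlation_p = p
    except ValueError as e:
        report.notes.append(f"per-field correlation skipped: {e}")

    # robustness filters re-run the first-bin test on the surviving subset
    for mode in ("kurtosis_ge_15", "peak_sf_gt_0.025", "roi_top_80pct"):
        try:
            idx = clustering.robustness_filter(
                cells_table, mode,
                kurtosis_threshold=cl.kurtosis_threshold,
                peak_sf_threshold_cpd=cl.peak_sf_threshold_cpd,
                roi_keep_fraction=cl.roi_keep_fraction,
            )
            sub = clustering.build_pair_table(
                kernels[idx], positions[idx],
                pref_orientation_deg=cells_table["pref_orientation_deg"].to_numpy()[idx],
                pref_sf_cpd=cells_table["pref_sf_cpd"].to_numpy()[idx],
            )
            c = clustering.bin_similarity(sub, edges)
            report.filter_first_bin_p[mode] = float(c.ranksum_p_vs_last[0])
        except ValueError as e:
            report.notes.append(f"filter {mode} skipped: {e}")

    depths = np.unique(positions[:, 2])
    if len(depths) > 1:
        levels = sorted({float(abs(a - b)) for a in depths for b in depths})
        curves = clustering.depth_similarity_analysis(pt, levels, edges)
        report.depth_first_bin_p = {
            str(dz): float(c.ranksum_p_vs_last[0]) for dz, c in curves.items()
        }


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    in_path=None,
) -> RunReport:
    """Run the full analysis; returns the report (also written as JSON).

    With ``config.simulate.enabled`` a synthetic dataset is generated;
    otherwise ``in_path`` must point to an existing trace container.
    Deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config_hash=config.config_hash(),
                       seed=config.seed)
    log.info("run: config_hash=%s seed=%d", report.config_hash, config.seed)

    # --- acquire data ----------------------------------------------------
    stimulus: StimulusSequence
    if config.simulate.enabled:
        s = config.simulate
        sheet = SheetConfig(
            n_cells=s.n_cells, field_um=s.field_um,
            plane_depths_um=tuple(s.plane_depths_um),
            map_length_um=s.map_length_um,
            column_decorrelation=s.column_decorrelation,
            interneuron_fraction=s.interneuron_fraction,
            low_sf_bias_weight=s.low_sf_bias_weight,
            seed=config.seed,
        )
        ds = generate_dataset(
            sheet, ResponseConfig(tau_half_ms=config.calcium.tau_half_ms),
            duration_s=config.stimulus.duration_s,
            update_rate_hz=config.stimulus.update_rate_hz,
            sf_max_cpd=config.stimulus.sf_max_cpd,
            imaging_rate_hz=config.imaging_rate_hz,
            n_lags=config.fit.n_lags,
            screen=ScreenGeometry(config.screen.width_cm, config.screen.height_cm,
                                  config.screen.distance_cm),
            seed=config.seed,
        )
        traces = ds.to_trace_set()
        stimulus, running, design = ds.stimulus, ds.running, ds.design
        io.write_traces(out / "dataset.h5", traces, stimulus, running, seed=config.seed)
        stimulus.to_csv(out / "stimulus.csv")
    elif in_path is not None:
        traces, stimulus, running = io.read_traces(in_path)
        if stimulus is None:
            raise StageError("load", "input container has no stimulus log")
        design = build_design(stimulus, config.imaging_rate_hz, config.fit.n_lags,
                              n_frames=traces.n_frames)
    else:
        raise StageError("load", "no input: enable simulate or pass a container path")
    report.n_cells = traces.n_cells
    report.n_frames = traces.n_frames

    # --- preprocess -------------------------------------------------------
    try:
        model = CalciumModel(config.calcium.tau_half_ms, config.imaging_rate_hz,
                             config.calcium.n_spline_knots)
        preprocess_traces(traces, model)
    except Exception as e:
        raise StageError("preprocess", str(e)) from e
    io.write_cells_csv(out / "cells_qc.csv", traces)

    # --- fit --------------------------------------------------------------
    try:
        fit_cfg = _fit_config(config)
        cd = _CellDesign(design, running, fit_cfg.n_lags)
        fits = [fit_cell(traces.inferred_spikes[i], cd, config=fit_cfg)
                for i in range(traces.n_cells)]
    except Exception as e:
        raise StageError("fit", str(e)) from e
    table = io.fits_table(fits)
    qc = traces.qc_table()
    table["kurtosis"] = qc["kurtosis"]
    table["roi_area_um2"] = qc["roi_area_um2"]
    table.to_csv(out / "fits.csv", index=False)
    io.write_kernels(out / "dataset.h5" if config.simulate.enabled else out / "kernels.h5",
                     np.stack([f.w for f in fits]), np.stack([f.v for f in fits]))

    # --- select -----------------------------------------------------------
    accepted, kept = select_cells(fits, config.fit.r_L_threshold,
                                  config.selection.min_cells)
    report.n_significant = len(kept)
    report.field_accepted = bool(accepted)
    if not accepted:
        report.notes.append(
            f"field rejected: {len(kept)} cells with r_L >= "
            f"{config.fit.r_L_threshold} (need > {config.selection.min_cells}); "
            "clustering skipped"
        )
        report.to_json(out / "report.json")
        return report

    # --- cluster ----------------------------------------------------------
    try:
        kernels = np.stack([fits[i].w for i in kept])
        positions = np.column_stack([
            traces.centroid_um[kept], traces.depth_um[kept]
        ])
        cluster_cells(kernels, positions, table.iloc[kept].reset_index(drop=True),
                      config, config.seed, report, out_dir=out)
    except Exception as e:
        raise StageError("cluster", str(e)) from e

    report.to_json(out / "report.json")
    return report
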