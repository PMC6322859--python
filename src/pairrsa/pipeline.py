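"""Top-level pipeline: simulate -> preprocess -> spatial -> temporal -> source.

The stage order mirrors the analysis logic: the spatial similarity stage
establishes the supra-threshold analysis window (auto-detected from the
combined within/between series, or set manually), and the temporal and
source stages are restricted to that window. Identical config + seed
yields identical outputs; a run manifest records the config hash, seeds
and output checksums.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as dsn
from . import source as src
from . import spatial, temporal
from .containers import SensorNeighborGraph
from .io import RunManifest, write_epochs, write_layout_csv
from .preprocess import FilterSpec, SmoothSpec, detrend_linear, lowpass
from .stats import PermutationPlan
from .synthetic import SimulationConfig, make_forward_model, simulate_dataset

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Demo-scale configuration (small enough for a desk run)."""
    return dict(
        simulation=dict(
            n_participants=8,
            n_pairs=20,
            n_sensors=32,
            sample_rate=300.0,
            epoch_window=[-2.0, 2.0],
        ),
        preprocess=dict(lowpass_hz=30.0, detrend=True),
        spatial=dict(
            threshold=0.04,
            search_interval=[-1.0, 0.0],
            window="auto",  # or [start_s, end_s]
            matrix_interval=[-1.0, 0.0],
            target_rate=300.0,
            n_perm=200,
        ),
        temporal=dict(radius_mm=40.0, n_perm=200),
        source=dict(n_grid=27, n_perm=200, covariance_window=[-1.0, 1.0]),
        save_epochs=False,
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, out_dir, seed: int = 0) -> dict:
    """Execute the full analysis chain; returns a results dict and writes
    CSV/JSON outputs plus the run manifest under ``out_dir``."""
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)
    rng_seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)

    # --- simulate -------------------------------------------------------
    sim_kwargs = dict(cfg["simulation"])
    for key in ("epoch_window", "effect_window", "word_onsets"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim_cfg = SimulationConfig(**sim_kwargs, seed=int(rng_seeds[0]))
    epoch_sets, truth = simulate_dataset(sim_cfg)
    design = truth.design
    layout_path = out / "sensor_layout.csv"
    write_layout_csv(truth.sensor_positions, layout_path,
                     sensor_ids=epoch_sets[0].sensor_ids)
    design_path = out / "design.csv"
    design.to_csv(design_path)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(truth.summary(), indent=1))
    stage_outputs = dict(layout=layout_path, design=design_path, ground_truth=gt_path)
    if cfg.get("save_epochs"):
        for es in epoch_sets:
            p = out / f"epochs_p{es.participant:02d}.h5"
            write_epochs(es, p)
            stage_outputs[f"epochs_p{es.participant:02d}"] = p
    manifest.add_stage("simulate", outputs=stage_outputs,
                       info=dict(seed=int(rng_seeds[0])))

    # --- preprocess -----------------------------------------------------
    pp = cfg["preprocess"]
    processed = []
    for es in epoch_sets:
        if pp.get("detrend", True):
            es = detrend_linear(es)
        if pp.get("lowpass_hz"):
            es = lowpass(es, FilterSpec(cutoff=float(pp["lowpass_hz"])))
        processed.append(es)
    manifest.add_stage("preprocess", info=dict(**pp))

    # --- spatial RSA ----------------------------------------------------
    sp = cfg["spatial"]
    within = dsn.enumerate_within(design)
    between = dsn.enumerate_between(design)
    _, within_group = spatial.average_condition_series(processed, within)
    _, between_group = spatial.average_condition_series(processed, between)
    combined = spatial.SimilarityTimeSeries(
        r=0.5 * (within_group.r + between_group.r),
        times=within_group.times,
        label="combined",
    )
    series_path = out / "similarity_series.csv"
    pd.DataFrame(
        dict(time_s=combined.times, r_within=within_group.r,
             r_between=between_group.r, r_combined=combined.r)
    ).to_csv(series_path, index=False)

    search = tuple(sp["search_interval"])
    detected = spatial.detect_window(combined, threshold=float(sp["threshold"]),
                                     search_interval=search)
    if sp.get("window", "auto") != "auto":
        window = tuple(sp["window"])
    elif detected is not None:
        window = detected
    else:
        window = tuple(sim_cfg.effect_window)  # fallback: nominal effect window
    w_means = spatial.condition_window_means(processed, within, window)
    b_means = spatial.condition_window_means(processed, between, window)
    wres = spatial.window_test(w_means, b_means, window)

    between_sub = dsn.subsample_between(between, len(within), seed=int(rng_seeds[1]))
    within_mats = spatial.average_condition_matrices(
        processed, within, tuple(sp["matrix_interval"]),
        target_rate=float(sp["target_rate"]), smooth=SmoothSpec())
    between_mats = spatial.average_condition_matrices(
        processed, between_sub, tuple(sp["matrix_interval"]),
        target_rate=float(sp["target_rate"]), smooth=SmoothSpec())
    mat_res = spatial.matrix_cluster_test(
        within_mats, between_mats,
        plan=PermutationPlan(n_perm=int(sp["n_perm"]), seed=int(rng_seeds[1])))
    spatial_json = out / "spatial_results.json"
    spatial_json.write_text(json.dumps(dict(
        detected_window=list(detected) if detected else None,
        analysis_window=list(window),
        mean_r_within=wres.mean_r_within,
        mean_r_between=wres.mean_r_between,
        t=wres.t_statistic, df=wres.df, p=wres.p_value,
        matrix_cluster_p=min((c.p_value for c in mat_res.clusters), default=None),
        n_matrix_clusters=len(mat_res.clusters),
    ), indent=1))
    manifest.add_stage("spatial_rsa",
                       outputs=dict(series=series_path, results=spatial_json))

    # --- temporal RSA ---------------------------------------------------
    tp = cfg["temporal"]
    graph = SensorNeighborGraph.from_positions(
        truth.sensor_positions, radius=float(tp["radius_mm"]),
        sensor_ids=epoch_sets[0].sensor_ids)
    w_maps, w_map_group = temporal.average_condition_maps(processed, within, window)
    b_maps, b_map_group = temporal.average_condition_maps(processed, between, window)
    sens_res = temporal.sensor_cluster_test(
        w_maps, b_maps, graph,
        plan=PermutationPlan(n_perm=int(tp["n_perm"]), seed=int(rng_seeds[2])))
    maps_path = out / "temporal_maps.csv"
    pd.DataFrame(dict(
        sensor_id=epoch_sets[0].sensor_ids,
        r_within=w_map_group.r_per_sensor,
        r_between=b_map_group.r_per_sensor,
        diff=w_map_group.r_per_sensor - b_map_group.r_per_sensor,
    )).to_csv(maps_path, index=False)
    temporal_json = out / "temporal_results.json"
    temporal_json.write_text(json.dumps(dict(
        sensor_cluster_p=min((c.p_value for c in sens_res.clusters), default=None),
        n_clusters=len(sens_res.clusters),
        largest_cluster_size=max((len(c.members) for c in sens_res.clusters),
                                 default=0),
    ), indent=1))
    manifest.add_stage("temporal_rsa",
                       outputs=dict(maps=maps_path, results=temporal_json))

    # --- source RSA -----------------------------------------------------
    so = cfg["source"]
    fm = make_forward_model(int(so["n_grid"]), truth.sensor_positions,
                            seed=int(rng_seeds[3]))
    cov_win = tuple(so["covariance_window"])
    cov_win = (max(cov_win[0], float(processed[0].times[0])),
               min(cov_win[1], float(processed[0].times[-1])))
    projected = []
    for es in processed:
        cov = src.estimate_covariance(es, cov_win)
        filt = src.lcmv_filters(fm, cov)
        projected.append(src.project_orientation(filt, es))
    res = src.source_temporal_rsa(projected, within, between, window,
                                  fm.grid_positions)
    grid_res = src.grid_cluster_test(
        res["within_maps"], res["between_maps"], fm,
        plan=PermutationPlan(n_perm=int(so["n_perm"]), seed=int(rng_seeds[3])))
    best = max(grid_res.clusters, key=lambda c: abs(c.mass), default=None)
    peak = (src.peak_region(res["difference"], best.members).tolist()
            if best is not None and best.tail == "positive" else [])
    source_path = out / "source_maps.csv"
    pd.DataFrame(dict(
        x=fm.grid_positions[:, 0], y=fm.grid_positions[:, 1],
        z=fm.grid_positions[:, 2],
        r_within=res["within"].values, r_between=res["between"].values,
        diff=res["difference"].values,
    )).to_csv(source_path, index=False)
    source_json = out / "source_results.json"
    source_json.write_text(json.dumps(dict(
        grid_cluster_p=min((c.p_value for c in grid_res.clusters), default=None),
        peak_region=peak,
        peak_grid_point=int(np.nanargmax(res["difference"].values)),
    ), indent=1))
    manifest.add_stage("source_rsa",
                       outputs=dict(maps=source_path, results=source_json))

    manifest.save(out / "manifest.json")
    return dict(
        window=window,
        detected_window=detected,
        window_result=wres,
        matrix_cluster=mat_res,
        sensor_cluster=sens_res,
        grid_cluster=grid_res,
        source=res,
        forward=fm,
        manifest=manifest,
    )
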