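"""Figure-level experiment orchestration at configurable scale.

Each experiment trains (or loads cached) reduced ensembles, runs the relevant
analyses, and writes tidy CSV tables plus a JSON summary and a run manifest
into an artifact directory. "reduced" scale uses 64-unit networks and small
ensembles; "full" mirrors the original study scale (256 units, 50 models per
condition) and is not intended for desk runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .task_env import COMMON_COLORS, EnvironmentPrior
from .training import train_ensemble
from . import behavior, cross_decoding, occupancy_theory, post_delay, state_geometry

EXPERIMENTS = ("fig1_behavior", "fig2_crossdecode", "fig3_geometry",
               "fig4_decomposition", "fig5_postdelay", "s7_noise_sweep",
               "s9_isolation")

SCALES = {
    "reduced": dict(n_rec=64, n_models=4, n_trials=1000,
                    updates=(800, 1500, 800, 1200)),
    "full": dict(n_rec=256, n_models=50, n_trials=5000,
                 updates=(8000, 15000, 8000, 12000)),
}


def _manifest(path: Path, name: str, scale: str, seed: int, config: dict):
    blob = json.dumps(dict(name=name, scale=scale, seed=seed, config=config),
                      sort_keys=True, default=str)
    man = dict(name=name, scale=scale, seed=seed, config=config,
               config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
               timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    path.mkdir(parents=True, exist_ok=True)
    (path / "manifest.json").write_text(json.dumps(man, indent=2, default=str))
    return man


def _get_pools(cfg: dict, seed: int, priors: dict):
    return train_ensemble(priors, cfg["n_models"], base_seed=seed,
                          n_rec=cfg["n_rec"], updates=cfg["updates"])


def run_experiment(name: str, scale: str = "reduced", out_dir="artifacts",
                   seed: int = 0, config: dict | None = None) -> Path:
    """Run one named experiment; returns the artifact directory."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; valid: {EXPERIMENTS}")
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; valid: {tuple(SCALES)}")
    cfg = dict(SCALES[scale])
    cfg.update(config or {})
    out = Path(out_dir) / name
    _manifest(out, name, scale, seed, cfg)
    summary: dict = {}
    rng = np.random.default_rng(seed)

    if name == "fig1_behavior":
        pools = _get_pools(cfg, seed, {"biased": EnvironmentPrior(sigma_s=25.0)})
        rows = []
        all_outputs = []
        for i, m in enumerate(pools["biased"]):
            for delay in (100.0, 1000.0):
                ins, outs = behavior.run_trials(m, cfg["n_trials"], delay, rng)
                err = behavior.circular_error(ins, outs)
                slope, _ = behavior.attraction_slope(m, data=(ins, outs))
                rows.append(dict(model=i, delay_ms=delay,
                                 rmse=behavior.rmse_from_errors(err).rmse,
                                 slope=slope))
                if delay == 1000.0:
                    all_outputs.append(outs)
        df = pd.DataFrame(rows)
        df.to_csv(out / "behavior.csv", index=False)
        peaks = behavior.count_histogram_peaks(np.concatenate(all_outputs))
        summary = dict(n_output_peaks=int(peaks),
                       rmse_by_delay=df.groupby("delay_ms")["rmse"].mean().to_dict(),
                       mean_slope=float(df["slope"].mean()))

    elif name == "fig2_crossdecode":
        pools = _get_pools(cfg, seed, {
            "biased": EnvironmentPrior(sigma_s=12.5),
            "uniform": EnvironmentPrior(uniform=True)})
        per_model = pd.DataFrame([
            dict(label=lab, model=i,
                 rmse=behavior.memory_error(m, 40.0, cfg["n_trials"], 800.0,
                                            rng).rmse)
            for lab, ms in pools.items() for i, m in enumerate(ms)])
        per_model.to_csv(out / "memory_error.csv", index=False)
        tables = []
        for matcher in ("rts", "rank"):
            t = cross_decoding.cross_decode_experiment(
                pools["biased"], pools["uniform"], matcher=matcher,
                n_pairs=max(4, cfg["n_models"]), rng=rng)
            tables.append(t)
        table = pd.concat(tables)
        table.to_csv(out / "crossdecode.csv", index=False)
        summary = {m: table.query("matcher == @m").groupby("combo")["rmse"]
                   .median().to_dict() for m in ("rts", "rank")}

    elif name == "fig3_geometry":
        pools = _get_pools(cfg, seed, {"biased": EnvironmentPrior(sigma_s=12.5)})
        rows, att_colors = [], []
        for i, m in enumerate(pools["biased"]):
            cum_full = state_geometry.dimensionality(m.params, 500, "full_trial")
            cum_delay = state_geometry.dimensionality(m.params, 500, "delay_only")
            seeds = state_geometry.delay_start_seeds(m.params, 100)
            plane = state_geometry.fit_delay_plane(m.params, rng=rng)
            fps = state_geometry.find_fixed_points(m.params, seeds,
                                                   ring_filter=plane)
            cols = state_geometry.attractor_colors(m.params, fps)
            att_colors.extend(np.asarray(cols).tolist())
            rows.append(dict(model=i, var3_full=float(cum_full[2]),
                             var2_delay=float(cum_delay[1]),
                             n_attractors=sum(f.kind == "attractor" for f in fps),
                             n_saddles=sum(f.kind == "saddle" for f in fps)))
        df = pd.DataFrame(rows)
        df.to_csv(out / "geometry.csv", index=False)
        summary = dict(mean_var3_full=float(df["var3_full"].mean()),
                       mean_var2_delay=float(df["var2_delay"].mean()),
                       attractor_colors=att_colors)

    elif name == "fig4_decomposition":
        sigmas = cfg.get("sigma_s_list", (3.0, 12.5, 25.0))
        pools = _get_pools(cfg, seed, {f"sigma_{s:g}": EnvironmentPrior(sigma_s=s)
                                       for s in sigmas})
        table = occupancy_theory.sweep_conditions(pools, rng=rng)
        table.to_csv(out / "decomposition.csv", index=False)
        summary = table.groupby("condition")[["dispersion", "occupancy",
                                              "theory_rmse", "experiment_rmse"]] \
            .median().to_dict()

    elif name == "fig5_postdelay":
        sigmas = cfg.get("sigma_s_list", (3.0, 12.5))
        priors = {f"sigma_{s:g}": EnvironmentPrior(sigma_s=s) for s in sigmas}
        priors["uniform"] = EnvironmentPrior(uniform=True)
        pools = _get_pools(cfg, seed, priors)
        rows = []
        for lab, ms in pools.items():
            for i, m in enumerate(ms):
                go = post_delay.evolve_go_ring(m.params, 1000, rng)
                resp = post_delay.evolve_response_ring(m.params, 1000, rng)
                occ = post_delay.readout_occupancy(m.params, rng=rng)
                rows.append(dict(condition=lab, model=i, cv_go=go.cv,
                                 cv_rep=resp.cv,
                                 cv_occ=post_delay.binned_cv(
                                     occ.occupancy, is_angles=False)))
        df = pd.DataFrame(rows)
        df.to_csv(out / "postdelay.csv", index=False)
        summary = df.groupby("condition")[["cv_go", "cv_rep", "cv_occ"]] \
            .mean().to_dict()

    elif name == "s7_noise_sweep":
        noises = cfg.get("noise_list", (0.1, 0.3))
        rows = []
        for nz in noises:
            pool = train_ensemble({"biased": EnvironmentPrior(sigma_s=17.5)},
                                  cfg["n_models"], base_seed=seed,
                                  n_rec=cfg["n_rec"], sigma=nz,
                                  updates=cfg["updates"])["biased"]
            for i, m in enumerate(pool):
                ac = occupancy_theory.angular_occupancy(m.params, rng=rng)
                occ_c = np.mean([ac.occupancy_at(c) for c in COMMON_COLORS])
                rows.append(dict(noise=nz, model=i, occupancy_common=occ_c))
        df = pd.DataFrame(rows)
        df.to_csv(out / "noise_sweep.csv", index=False)
        summary = df.groupby("noise")["occupancy_common"].mean().to_dict()

    elif name == "s9_isolation":
        pools = _get_pools(cfg, seed, {
            "biased": EnvironmentPrior(sigma_s=3.0),
            "uniform": EnvironmentPrior(uniform=True)})
        rows = []
        for lab, ms in pools.items():
            for i, m in enumerate(ms):
                chain = post_delay.build_angle_chain(m.params, 130.0, rng=rng)
                for proc in ("go", "response", "readout"):
                    rows.append(dict(condition=lab, model=i, process=proc,
                                     rmse=post_delay.isolate_process(
                                         m.params, proc, chain)))
        df = pd.DataFrame(rows)
        df.to_csv(out / "isolation.csv", index=False)
        summary = df.groupby(["condition", "process"])["rmse"].median().to_dict()

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=str))
    return out
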