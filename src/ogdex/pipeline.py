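"""End-to-end pipeline: simulate -> index -> fit -> validate -> map.

Driven by a YAML run configuration; every stage writes its artifacts
into the output directory and a ``manifest.json`` records seeds,
configuration, the epsilon rule, the covariate scaler and convergence
diagnostics, so any output is regenerable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import hierarchical_model as hm
from . import prediction, synthetic_data, tables, validation
from .raster import RasterGrid, write_esri_ascii

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "generator": {"n_plots": 500},
    "fit": {"n_chains": 3, "burn_in": 500, "iterations": 2000,
            "max_extension_rounds": 2},
    "validation": {"n_reps": 5, "train_fraction": 0.9},
    "map": {"shape": [40, 40], "cell_size": 20.0, "target": 0.5},
}


def load_config(path: str | Path | None) -> dict:
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _fit_config(config: dict) -> hm.FitConfig:
    fc = config.get("fit", {})
    return hm.FitConfig(
        n_chains=int(fc.get("n_chains", 3)),
        burn_in=int(fc.get("burn_in", 1000)),
        iterations=int(fc.get("iterations", 10_000)),
        max_extension_rounds=int(fc.get("max_extension_rounds", 3)),
        seed=int(config.get("seed", 0)),
    )


def _synthetic_covariate_stack(
    samples, shape, cell_size, seed
) -> dict[str, RasterGrid]:
    """Covariate rasters drawn from the same stated world as the samples."""
    gcfg = replace(
        synthetic_data.GeneratorConfig(), n_plots=shape[0] * shape[1], seed=seed
    )
    cov = synthetic_data.gen_covariates(gcfg)
    return {
        name: RasterGrid(cov[name].to_numpy().reshape(shape), cell_size)
        for name in cov.columns
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage artifacts: ``samples.csv`` (simulated plot samples with index),
    ``chains.csv`` + side-car (posterior draws), ``summary.csv``,
    ``cv.json``, ``t_target.asc`` and ``index_map.asc``.  Any stage
    failure leaves earlier artifacts in place and a manifest marking
    the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "config": config, "status": "running",
                      "artifacts": {}}
    try:
        # simulate
        gen_cfg = synthetic_data.GeneratorConfig(
            n_plots=int(config["generator"].get("n_plots", 500)), seed=seed
        )
        samples = synthetic_data.gen_plot_samples(gen_cfg)
        tables.write_table(samples, out / "samples.csv")
        manifest["artifacts"]["samples"] = "samples.csv"

        # fit
        fit_cfg = _fit_config(config)
        fit = hm.fit(samples, "I_og", fit_cfg)
        tables.write_chains(fit, out / "chains.csv")
        fit.summary().to_csv(out / "summary.csv")
        manifest["artifacts"]["chains"] = "chains.csv"
        manifest["artifacts"]["summary"] = "summary.csv"
        manifest["epsilon"] = {
            "eps_low": fit.epsilon.eps_low, "eps_high": fit.epsilon.eps_high
        }
        manifest["scaler"] = {"mean": fit.scaler.mean, "sd": fit.scaler.sd}
        manifest["rhat_max"] = max(fit.convergence.rhat.values())
        manifest["converged"] = fit.convergence.converged

        # validate
        vcfg = config.get("validation", {})
        cv = validation.holdout_cv(
            samples,
            "I_og",
            train_fraction=float(vcfg.get("train_fraction", 0.9)),
            n_reps=int(vcfg.get("n_reps", 5)),
            seed=seed,
            fit_config=fit_cfg,
        )
        r2_full = validation.r_squared(fit, samples)
        with open(out / "cv.json", "w") as fh:
            json.dump(
                {
                    "r2_training": r2_full,
                    "cv_mean": cv.mean,
                    "cv_sd": cv.sd,
                    "per_rep": cv.r2.tolist(),
                    "skipped": cv.skipped,
                },
                fh,
                indent=2,
            )
        manifest["artifacts"]["cv"] = "cv.json"
        manifest["r2_training"] = r2_full

        # map
        mcfg = config.get("map", {})
        shape = tuple(mcfg.get("shape", (40, 40)))
        cell = float(mcfg.get("cell_size", 20.0))
        target = float(mcfg.get("target", 0.5))
        stack = _synthetic_covariate_stack(samples, shape, cell, seed + 17)
        clamp = prediction.ClampRule.from_training(samples)
        params = fit.params("mean")
        t_map = prediction.map_t_target(stack, params, fit.scaler, clamp, target)
        write_esri_ascii(t_map, out / "t_target.asc")
        age = RasterGrid(np.full(shape, 50.0), cell)
        idx_map = prediction.map_index(stack, age, None, params, fit.scaler, clamp)
        write_esri_ascii(idx_map, out / "index_map.asc")
        manifest["artifacts"]["t_target"] = "t_target.asc"
        manifest["artifacts"]["index_map"] = "index_map.asc"
        manifest["t_target_sentinel_unreachable"] = prediction.UNREACHABLE
        reach = t_map.values[np.isfinite(t_map.values)]
        reach = reach[reach != prediction.UNREACHABLE]
        manifest["t_target_median"] = float(np.median(reach)) if reach.size else math.nan

        manifest["status"] = "ok"
    except Exception as exc:  # partial outputs retained, failure recorded
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
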