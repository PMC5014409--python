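"""End-to-end pipeline orchestration with reproducible configuration.

Stages: simulate (optional) -> realign -> expand -> filter -> fit stage 1
-> residual stage 2 -> map -> report.  Every artifact is written under a
run directory together with a manifest capturing the seeds, a hash of the
resolved configuration and the package version, so re-running an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import realign_point_covariate, realign_raster_covariate
from .design import expand_terms, filter_mccm
from .ensemble import (fit_ensemble, make_splits, model_average_predict,
                       plot_selection_frequencies, selection_frequencies,
                       vsepe_summary, run_method_comparison)
from .grids import PointSet, read_esri_ascii, write_esri_ascii
from .mapping import (plot_map, predict_full_cover, rasterize_point_survey,
                      uncertainty_raster)
from .spatialpoly import SpatialDesignSpec, fit_residual_stage
from .synth import SceneConfig, generate_scene, write_scene

log = logging.getLogger("larmap")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},          # SceneConfig overrides live here
    "realign": {"pixel_size": 25.0, "array_dim": 100},
    "design": {"max_order": 4},
    "filter": {"mccm": 0.95},
    "fit": {"n_splits": 500, "n_train": 35, "methods": ["lar"]},
    "spatial": {"max_single_order": 12, "max_total_interaction_order": 6,
                "reuse_stage1_splits": False},
    "map": {"level": 0.95},
    "inputs": {},                            # response/surveys/rasters paths
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _validate_keys(user)
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _validate_keys(user: dict) -> None:
    problems = [k for k in user if k not in DEFAULT_CONFIG]
    if problems:
        raise ValueError(
            "unknown configuration section(s): " + ", ".join(sorted(problems))
            + f"; known sections are {sorted(DEFAULT_CONFIG)}"
        )


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(cfg: dict):
    inputs = cfg["inputs"]
    for key in ("response",):
        if key not in inputs:
            raise FileNotFoundError("config inputs.response is required when "
                                    "simulation is disabled")
    rp = Path(inputs["response"])
    if not rp.exists():
        raise FileNotFoundError(f"response table not found: {rp}")
    response = PointSet.from_csv(rp)
    surveys = {}
    for p in map(Path, inputs.get("surveys", [])):
        if not p.exists():
            raise FileNotFoundError(f"survey table not found: {p}")
        ps = PointSet.from_csv(p)
        surveys[ps.values.columns[0]] = ps
    rasters = {}
    for p in map(Path, inputs.get("rasters", [])):
        if not p.exists():
            raise FileNotFoundError(f"raster not found: {p}")
        rasters[p.stem.removeprefix("raster_")] = read_esri_ascii(p)
    return response, surveys, rasters


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.time()
    timings: dict[str, float] = {}
    seed = int(cfg["seed"])

    def stage(name):
        log.info("stage %s ...", name)
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    # --- simulate or load -------------------------------------------------
    stage("simulate")
    scene = None
    if cfg["simulate"].get("enabled", False):
        sc_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
        sc_kwargs.setdefault("seed", seed)
        if "true_term_kinds" in sc_kwargs:
            sc_kwargs["true_term_kinds"] = tuple(sc_kwargs["true_term_kinds"])
        scene = generate_scene(SceneConfig(**sc_kwargs))
        write_scene(scene, out / "scene")
        response = scene.response
        surveys = scene.point_surveys
        rasters = dict(scene.rasters)
    else:
        response, surveys, rasters = _load_inputs(cfg)
    done("simulate")

    y = response.values.iloc[:, 0].to_numpy(dtype=float)

    # --- realign ----------------------------------------------------------
    stage("realign")
    px = float(cfg["realign"]["pixel_size"])
    adim = int(cfg["realign"]["array_dim"])
    base = {}
    for nm, ps in surveys.items():
        base[nm] = realign_point_covariate(ps, nm, response.coords, px, adim)
    for nm, rg in rasters.items():
        base[nm] = realign_raster_covariate(rg, response.coords, px, adim)
    base_table = pd.DataFrame(base)
    base_table.to_csv(out / "realigned_covariates.csv", index=False)
    done("realign")

    # --- expand + filter --------------------------------------------------
    stage("expand")
    design = expand_terms(base_table, max_order=int(cfg["design"]["max_order"]))
    done("expand")
    stage("filter")
    filtered = filter_mccm(design, float(cfg["filter"]["mccm"]), seed=seed)
    filtered.filter_log.to_csv(out / "filter_log.csv", index=False)
    done("filter")

    # --- stage 1 fit ------------------------------------------------------
    stage("fit")
    plan = make_splits(len(response), n_train=int(cfg["fit"]["n_train"]),
                       n_splits=int(cfg["fit"]["n_splits"]), seed=seed)
    methods = tuple(cfg["fit"]["methods"])
    summary, ensembles = run_method_comparison(
        filtered, y, plan, methods=methods, mccm_levels=(float(cfg["filter"]["mccm"]),),
        filter_seed=seed,
    ) if len(methods) > 1 else (None, None)
    if ensembles is None:
        ens1 = fit_ensemble(filtered, y, plan, method=methods[0])
    else:
        ens1 = ensembles[(methods[0], float(cfg["filter"]["mccm"]))]
    s1 = vsepe_summary(ens1, filtered, y)
    freq = selection_frequencies(ens1)
    freq.to_csv(out / "selection_frequencies.csv", index=False)
    plot_selection_frequencies(ens1, out / "selection_frequencies.png")
    if summary is not None:
        summary.to_csv(out / "method_comparison.csv", index=False)
    done("fit")

    # --- stage 2 residual surface ----------------------------------------
    stage("residual")
    map1 = model_average_predict(ens1, filtered.matrix)
    resid = y - map1
    sp_cfg = cfg["spatial"]
    spec2 = SpatialDesignSpec(int(sp_cfg["max_single_order"]),
                              int(sp_cfg["max_total_interaction_order"]))
    plan2 = plan if sp_cfg.get("reuse_stage1_splits") else None
    stage2 = fit_residual_stage(resid, response, spec2, plan=plan2,
                                seed=seed + 1, n_splits=int(cfg["fit"]["n_splits"]),
                                n_train=int(cfg["fit"]["n_train"]))
    done("residual")

    # --- map --------------------------------------------------------------
    stage("map")
    template = next(iter(rasters.values())) if rasters else None
    if template is not None:
        cov_rasters = dict(rasters)
        for nm, ps in surveys.items():
            cov_rasters[nm] = rasterize_point_survey(ps, nm, template)
        pred, stack = predict_full_cover(ens1, cov_rasters, filtered.terms, stage2)
        unc = uncertainty_raster(stack, template, level=float(cfg["map"]["level"]))
        write_esri_ascii(pred, out / "prediction.asc")
        write_esri_ascii(unc, out / "uncertainty.asc")
        plot_map(pred, out / "prediction.png", response, "model-averaged prediction")
        plot_map(unc, out / "uncertainty.png", None, "middle-95% prediction width")
    done("map")

    # --- report + manifest ------------------------------------------------
    timings["report"] = 0.0
    report = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": seed,
        "n_observations": len(response),
        "n_base_covariates": int(base_table.shape[1]),
        "n_expanded_terms": design.p,
        "n_filtered_terms": filtered.p,
        "stage1": {k: float(v) for k, v in s1.items()},
        "stage2_map_r2_on_residuals": float(
            1 - np.sum((resid - stage2.predict(response.coords)) ** 2)
            / max(np.sum((resid - resid.mean()) ** 2), 1e-300)
        ),
        "timings_s": timings,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = {"config": cfg, "config_hash": _config_hash(cfg),
                "version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete in %.2fs", time.time() - t_all)
    return out
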