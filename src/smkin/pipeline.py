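"""End-to-end pipeline: simulate -> track -> classify -> kinetics,
plus stoichiometry and escape-scan stages, driven by one flat config.

Config keys are namespaced (``sim.*``, ``track.*``, ``kin.*``,
``stoich.*``, ``escape.*``) with globals ``seed``, ``out`` and ``stages``.
Unknown keys raise immediately, naming the key. Every artifact embeds the
seed and the parameters that produced it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as sio
from .core import AcquisitionMeta
from .escape import EscapeConfig, scan_parameter_grid
from .kinetics import estimate_kinetics
from .sim import SimKineticParams, simulate_two_state_tracks
from .stoichiometry import estimate_stoichiometry
from .tracking import (classify_bound_segments, fit_mobility_mixture,
                       step_size_distribution)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

# Defaults are the experimental conditions of the source system: bilayer
# diffusion 0.44 um^2/s, off time 5.2 s with a 30 s bleach standard,
# feature/unit intensities 136.0 and 47 counts, 1:1 EGFP labeling.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": "smkin_out",
    "stages": ["sim", "track", "kinetics", "stoich"],
    "sim.n_tracks": 60,
    "sim.n_frames": 400,
    "sim.frame_interval": 0.1,
    "sim.exposure_time": 0.05,
    "sim.field_px": 128,
    "sim.pixel_size": 0.105,
    "sim.d_free": 0.44,
    "sim.d_bound": 0.005,
    "sim.v_radial": 0.05,
    "sim.k_bind": 0.5,
    "sim.k_off": 1 / 5.2,
    "sim.k_bl": 1 / 30.0,
    "track.lag": 1,
    "track.window": 3,
    "kin.tau_bl": 30.0,
    "kin.tau_bl_sem": 0.0,
    "kin.censor_policy": "exclude",
    "kin.min_duration": 0.3,
    "kin.dwells_csv": "",
    "stoich.feature_intensity": 136.0,
    "stoich.feature_sem": 0.04,
    "stoich.unit_intensity": 47.0,
    "stoich.unit_sem": 2.0,
    "stoich.labeled_fraction": 0.5,
    "escape.tau_off_grid": [5.2],
    "escape.cluster_grid": [1, 9, 25, 100],
    "escape.k_on_grid": [0.17],
    "escape.n_iter": 100,
}

_VALID_STAGES = ("sim", "track", "kinetics", "stoich", "escape")


def _merge_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown config key: {key!r}")
        cfg[key] = val
    for st in cfg["stages"]:
        if st not in _VALID_STAGES:
            raise KeyError(f"unknown stage: {st!r}")
    return cfg


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the selected stages in order; returns paths and summaries.

    Stage dependencies: ``track`` needs ``sim`` (or a tracks CSV already
    in the output directory); ``kinetics`` needs ``track`` dwells or an
    explicit ``kin.dwells_csv``. A missing upstream artifact raises a
    dependency error.
    """
    cfg = _merge_config(config)
    out = Path(out_dir or cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    report: dict = {"out": str(out), "seed": seed, "stages": stages}
    echo = {k: v for k, v in cfg.items() if k not in ("out",)}

    tracks = None
    dwells = None
    if "sim" in stages:
        n_px = int(cfg["sim.field_px"])
        meta = AcquisitionMeta(cfg["sim.frame_interval"],
                               cfg["sim.exposure_time"],
                               cfg["sim.pixel_size"], (n_px, n_px),
                               int(cfg["sim.n_frames"]))
        params = SimKineticParams(cfg["sim.d_free"], cfg["sim.d_bound"],
                                  cfg["sim.v_radial"], cfg["sim.k_bind"],
                                  cfg["sim.k_off"], cfg["sim.k_bl"])
        center = (meta.field_um[1] / 2, meta.field_um[0] / 2)
        tracks, truth = simulate_two_state_tracks(
            params, meta, int(cfg["sim.n_tracks"]), center, seed)
        sio.write_tracks_csv(out / "tracks.csv", tracks, {"config": echo})
        report["tracks_csv"] = str(out / "tracks.csv")
        logger.info("sim: %d tracks, %d true bound intervals", len(tracks),
                    len(truth.intervals))

    if "track" in stages:
        if tracks is None:
            p = out / "tracks.csv"
            if not p.exists():
                raise FileNotFoundError(
                    "stage 'track' needs tracks from stage 'sim' or an "
                    f"existing {p}")
            tracks = sio.read_tracks_csv(p)
        steps = step_size_distribution(tracks, int(cfg["track.lag"]))
        fit = fit_mobility_mixture(
            steps, int(cfg["track.lag"]) * tracks.meta.frame_interval)
        labeled, dwells = classify_bound_segments(
            tracks, fit, int(cfg["track.window"]))
        sio.write_tracks_csv(out / "tracks_labeled.csv", labeled,
                             {"config": echo})
        sio.write_dwells_csv(out / "dwells.csv", dwells, {"config": echo})
        report["dwells_csv"] = str(out / "dwells.csv")
        report["mobility_fit"] = {
            "n_components": fit.n_components, "d_slow": fit.d_slow,
            "d_fast": fit.d_fast, "f_slow": fit.f_slow, "r_star": fit.r_star}

    if "kinetics" in stages:
        if cfg["kin.dwells_csv"]:
            dwells = sio.read_dwells_csv(cfg["kin.dwells_csv"])
        elif dwells is None:
            p = out / "dwells.csv"
            if not p.exists():
                raise FileNotFoundError(
                    "stage 'kinetics' needs dwells from stage 'track' or "
                    "kin.dwells_csv")
            dwells = sio.read_dwells_csv(p)
        est = estimate_kinetics(dwells, float(cfg["kin.tau_bl"]),
                                float(cfg["kin.tau_bl_sem"]),
                                cfg["kin.censor_policy"],
                                float(cfg["kin.min_duration"]))
        summary = est.to_dict()
        summary["seed"] = seed
        summary["config"] = echo
        sio.write_json(out / "kinetics.json", summary)
        report["kinetics"] = est.to_dict()

    if "stoich" in stages:
        res = estimate_stoichiometry(
            float(cfg["stoich.feature_intensity"]),
            float(cfg["stoich.unit_intensity"]),
            float(cfg["stoich.labeled_fraction"]),
            float(cfg["stoich.feature_sem"]),
            float(cfg["stoich.unit_sem"]))
        d = res.to_dict()
        d["seed"] = seed
        d["config"] = echo
        sio.write_json(out / "stoich.json", d)
        report["stoichiometry"] = res.to_dict()

    if "escape" in stages:
        base = EscapeConfig(n_iter=int(cfg["escape.n_iter"]), seed=seed)
        table = scan_parameter_grid(cfg["escape.tau_off_grid"],
                                    cfg["escape.cluster_grid"],
                                    cfg["escape.k_on_grid"], base)
        sio.write_escape_csv(out / "escape.csv", table, {"config": echo})
        report["escape_csv"] = str(out / "escape.csv")

    return report
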