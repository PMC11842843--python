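"""Declarative end-to-end runs driven by a single YAML/JSON config.

A run bundle is deterministic for a given (config, seed): all numeric
tables are written with full float precision, and a manifest records the
config hash, seed, and package version.

Config schema (version 1)::

    version: 1
    seed: 1                      # mandatory when a generator is used
    out_dir: out/
    simulate:                    # either this ...
      preset: mixed              # malate-high | chloride-high | mixed
      duration_ns: 2000
    trajectory: traj.jsonl       # ... or this
    detect:
      offset_nm: 1.5
      species: [chloride, malate]
    current:
      voltage_mV: -500
      valence: {chloride: 1, malate: 2}
    sites:                       # optional occupancy stage
      S1: [-1.25, -0.75]
      S2: [-0.25, 0.25]
      S3: [0.75, 1.25]
    pore:                        # optional geometry stage
      pdb: structure.pdb
      step: 0.2
    kinetics:                    # optional fitting stage
      trace: trace.csv
      voltage_mV: -120
      pulse_start_ms: 0
      exclude_ms: 4
      window_end_ms: 2500
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io.events import write_events
from .core_io.traces import read_current_trace
from .core_io.trajectories import read_trajectory, write_trajectory
from .core_io.structures import read_structure
from .kinetics import fit_activation
from .permeation import (
    DetectorParams,
    SiteModel,
    detect_events,
    flux_summary,
    relative_influx_timing,
    segment_conductive_phases,
    site_occupancy,
)
from .pore_geometry import compute_radius_profile, find_constrictions
from .synthetic_data import preset_params, simulate_knockon, PRESETS

logger = logging.getLogger("channelflux.pipeline")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    problems = []
    if cfg.get("version") != 1:
        problems.append("version: must be 1")
    if "out_dir" not in cfg:
        problems.append("out_dir: required")
    has_sim = "simulate" in cfg
    has_traj = "trajectory" in cfg
    if has_sim and has_traj:
        problems.append("simulate/trajectory: exactly one input source per stage")
    if has_sim:
        if "seed" not in cfg:
            problems.append("seed: mandatory when a generator is used")
        preset = cfg["simulate"].get("preset")
        if preset not in PRESETS:
            problems.append(f"simulate.preset: must be one of {PRESETS}")
    if has_traj and not Path(cfg["trajectory"]).exists():
        problems.append(f"trajectory: missing input file {cfg['trajectory']}")
    det = cfg.get("detect", {})
    if det.get("offset_nm") is not None and det["offset_nm"] <= 0:
        problems.append("detect.offset_nm: must be positive")
    if "pore" in cfg and not Path(cfg["pore"].get("pdb", "")).exists():
        problems.append("pore.pdb: missing input file")
    if "kinetics" in cfg and not Path(cfg["kinetics"].get("trace", "")).exists():
        problems.append("kinetics.trace: missing input file")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    validate_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": _config_hash(cfg),
        "seed": cfg.get("seed"),
        "version": __version__,
        "stages": {},
    }

    traj = truth = None
    if "simulate" in cfg:
        sim = cfg["simulate"]
        params = preset_params(
            sim["preset"], seed=int(cfg["seed"]), duration_ns=float(sim.get("duration_ns", 2000.0))
        )
        traj, truth = simulate_knockon(params)
        write_trajectory(traj, out / "trajectory.jsonl")
        write_events(truth.events, out / "truth_events.csv")
        manifest["stages"]["simulate"] = {
            "preset": sim["preset"],
            "n_frames": int(traj.n_frames),
            "n_truth_events": len(truth.events),
        }
        logger.info("simulate: %d frames, %d truth events", traj.n_frames, len(truth.events))
    elif "trajectory" in cfg:
        traj = read_trajectory(cfg["trajectory"])
        manifest["stages"]["load"] = {"n_frames": int(traj.n_frames)}

    if traj is not None and "detect" in cfg:
        det = cfg["detect"]
        params = DetectorParams(
            boundary_offset_nm=float(det.get("offset_nm", 1.5)),
            species=det.get("species"),
        )
        events = detect_events(traj, params)
        write_events(events, out / "events.csv")
        duration = float(traj.times[-1] - traj.times[0])
        cur = cfg.get("current", {})
        valences = cur.get("valence", {"chloride": 1, "malate": 2})
        rows = []
        for sp in sorted({e.species for e in events}):
            for direction in ("influx", "efflux"):
                s = flux_summary(
                    events,
                    duration,
                    voltage_mV=float(cur.get("voltage_mV", 0.0)),
                    species=sp,
                    valence=int(valences.get(sp, 1)),
                    direction=direction,
                )
                rows.append(asdict(s))
        pd.DataFrame(rows).to_csv(out / "flux_summary.csv", index=False)
        phases = segment_conductive_phases(events, float(det.get("max_gap_ns", 50.0)))
        pd.DataFrame(
            [
                {
                    "start_ns": p.start_ns,
                    "end_ns": p.end_ns,
                    "n_events": p.n_events,
                    "flow_rate_per_us": p.flow_rate_per_us,
                }
                for p in phases
            ]
        ).to_csv(out / "phases.csv", index=False)
        manifest["stages"]["detect"] = {"n_events": len(events), "n_phases": len(phases)}
        logger.info("detect: %d events in %d phases", len(events), len(phases))

        if "sites" in cfg:
            model = SiteModel({k: tuple(v) for k, v in cfg["sites"].items()})
            occ = site_occupancy(traj, model)
            df = pd.DataFrame({"time_ns": occ.frame_times, **occ.counts})
            df.to_csv(out / "occupancy.csv", index=False)
            manifest["stages"]["occupancy"] = occ.mean_occupancy()

        cl = events.filter(species="chloride", direction="influx")
        mal = events.filter(species="malate", direction="influx")
        if len(cl) and len(mal):
            hist = relative_influx_timing(cl, mal, window_ns=float(det.get("lag_window_ns", 50.0)))
            pd.DataFrame(
                {"bin_lo_ns": hist.bin_edges_ns[:-1], "bin_hi_ns": hist.bin_edges_ns[1:], "count": hist.counts}
            ).to_csv(out / "lag_histogram.csv", index=False)
            manifest["stages"]["timing"] = {
                "n_lags": int(len(hist.lags_ns)),
                "n_no_antecedent": hist.n_no_antecedent,
            }

    if "pore" in cfg:
        pcfg = cfg["pore"]
        structure = read_structure(pcfg["pdb"])
        profile = compute_radius_profile(structure, step=float(pcfg.get("step", 0.2)))
        pd.DataFrame(
            {"z": profile.z, "x": profile.centers[:, 0], "y": profile.centers[:, 1], "radius": profile.radius}
        ).to_csv(out / "pore_profile.csv", index=False)
        cons = find_constrictions(profile)
        pd.DataFrame([{"z": c.z, "radius": c.radius} for c in cons]).to_csv(
            out / "constrictions.csv", index=False
        )
        manifest["stages"]["pore"] = {
            "min_radius": profile.min_radius(),
            "n_constrictions": len(cons),
        }

    if "kinetics" in cfg:
        kcfg = cfg["kinetics"]
        trace = read_current_trace(kcfg["trace"], voltage_mV=kcfg.get("voltage_mV"))
        fit = fit_activation(
            trace,
            pulse_start_ms=float(kcfg.get("pulse_start_ms", 0.0)),
            exclude_initial_ms=float(kcfg.get("exclude_ms", 4.0)),
            window_end_ms=kcfg.get("window_end_ms"),
        )
        with open(out / "activation_fit.json", "w") as fh:
            json.dump(fit.asdict(), fh, indent=2)
        manifest["stages"]["kinetics"] = {"converged": fit.converged, "residual_rms": fit.residual_rms}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
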