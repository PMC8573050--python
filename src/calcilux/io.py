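"""Artifact I/O: run configuration files, manifests, and the
simulate -> analyze -> report pipeline stages.

An artifact directory (produced by :func:`run_simulate`) holds the movie
stack (TIFF + JSON sidecar), the ground-truth event table, optional MEA and
photocurrent CSVs, and a manifest with checksums; re-running with the same
configuration and seed reproduces every file bit-identically.
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
from .config import PRESETS, SessionConfig
from .coupling import (coupling_calibration, fit_photocurrent, pair_events,
                       temporal_correlation)
from .events import (decay_fits_per_stimulus, detect_events, fidelity,
                     hourly_summary)
from .network import nap_by_window
from .roi import assign_rois
from .schedule import StimulationSchedule, empty_schedule
from .simulate import (MEARecording, mea_grid, simulate_mea,
                       simulate_photocurrent, simulate_session)
from .stack import MovieStack
from .traces import extract_traces

log = logging.getLogger("calcilux")


class ConfigError(ValueError):
    """A run configuration failed validation; message names the field."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> dict:
    """Read a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("run configuration must be a mapping")
    return cfg


def build_session_config(cfg: dict, seed: int | None = None) -> SessionConfig:
    """SessionConfig from a run configuration: preset base + overrides."""
    preset = cfg.get("preset", "invivo")
    if preset not in PRESETS:
        raise ConfigError(f"preset: unknown preset {preset!r} "
                          f"(choose from {sorted(PRESETS)})")
    overrides = dict(cfg.get("session", {}) or {})
    if seed is None:
        seed = int(cfg.get("seed", 0))
    try:
        return PRESETS[preset](seed=seed, **overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"session: {exc}") from exc


def build_schedule(cfg: dict, session: SessionConfig) -> StimulationSchedule:
    sched = cfg.get("schedule")
    if sched is None:
        if session.duration_h >= 1:
            return StimulationSchedule.hourly_blocks(
                hours=int(session.duration_h), per_hour=10)
        return empty_schedule()
    kind = sched.get("type", "periodic")
    kw = {k: v for k, v in sched.items() if k != "type"}
    try:
        if kind == "periodic":
            return StimulationSchedule.periodic(**kw)
        if kind == "hourly_blocks":
            return StimulationSchedule.hourly_blocks(**kw)
        if kind == "explicit":
            return StimulationSchedule(
                onsets_s=np.asarray(kw.pop("onsets_s"), dtype=float), **kw)
        if kind == "none":
            return empty_schedule()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"schedule: {exc}") from exc
    raise ConfigError(f"schedule.type: unknown type {kind!r}")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: dict, seed: int) -> Path:
    """Checksum every artifact file into ``manifest.json``."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "tool": "calcilux",
        "version": __version__,
        "seed": seed,
        "config": config,
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def run_simulate(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Simulate a session into an artifact directory.

    ``config`` is a run-configuration mapping or a path to a YAML/JSON file;
    writes stack.tif (+ .json sidecar), ground_truth_events.csv,
    cells.csv, optional mea.csv / photocurrent.csv, and manifest.json.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    session = build_session_config(config, seed=seed)
    schedule = build_schedule(config, session)

    stack, cellmap = simulate_session(session, schedule)
    stack.save(out_dir / "stack.tif", schedule=schedule,
               extra={"session": session.to_dict()})
    cellmap.save_events_csv(out_dir / "ground_truth_events.csv")
    cells = pd.DataFrame({
        "neuron_id": np.arange(cellmap.n_neurons),
        "row_px": cellmap.positions_px[:, 0],
        "col_px": cellmap.positions_px[:, 1],
        "radius_px": cellmap.radii_px,
        "responsive": cellmap.responsive,
    })
    cells.to_csv(out_dir / "cells.csv", index=False)

    mea_cfg = config.get("mea") or {}
    if mea_cfg.get("enabled"):
        extent = session.field_size * session.pixel_scale_um
        n_rows = int(mea_cfg.get("n_rows", 5))
        n_cols = int(mea_cfg.get("n_cols", 6))
        pitch = float(mea_cfg.get("pitch_um",
                                  extent / (max(n_rows, n_cols) + 1)))
        electrodes = mea_grid(n_rows, n_cols, pitch,
                              origin_um=(pitch / 2, pitch / 2))
        mea = simulate_mea(
            cellmap, electrodes,
            coupling_uv_per_pct=float(mea_cfg.get("coupling_uv_per_pct", 0.17)),
            noise_ratio=float(mea_cfg.get("noise_ratio", 0.1)),
            seed=session.seed + 1)
        mea.save_csv(out_dir / "mea.csv")
        np.savetxt(out_dir / "electrodes.csv", electrodes, delimiter=",",
                   header="y_um,x_um", comments="")

    pc_cfg = config.get("photocurrent") or {}
    if pc_cfg.get("enabled"):
        pulse = StimulationSchedule.periodic(
            1, 1.0, pulse_width_ms=float(pc_cfg.get("pulse_width_ms", 100.0)))
        trace = simulate_photocurrent(
            pulse,
            tau_on_ms=float(pc_cfg.get("tau_on_ms", 32.0)),
            tau_off_ms=float(pc_cfg.get("tau_off_ms", 68.0)),
            i_max_pa=float(pc_cfg.get("i_max_pa", 440.0)),
            noise_frac=float(pc_cfg.get("noise_frac", 0.0)),
            seed=session.seed + 2)
        trace.save_csv(out_dir / "photocurrent.csv")
        (out_dir / "photocurrent.json").write_text(
            json.dumps({"pulse": pulse.to_dict()}, indent=1))

    write_manifest(out_dir, config, session.seed)
    log.info("simulate: wrote %s in %.1f s", out_dir, time.monotonic() - t0)
    return out_dir


def load_mea_csv(path: str | Path) -> MEARecording:
    df = pd.read_csv(path)
    electrodes = (df[["electrode", "y_um", "x_um"]]
                  .drop_duplicates("electrode").sort_values("electrode"))
    n_e = int(df["electrode"].max()) + 1 if len(df) else 0
    pos = np.zeros((n_e, 2))
    pos[electrodes["electrode"].to_numpy()] = electrodes[["y_um", "x_um"]].to_numpy()
    spikes = df[["electrode", "t_s", "amplitude_uv"]].copy()
    if "event_idx" in df.columns:
        spikes["event_idx"] = df["event_idx"]
    return MEARecording(positions_um=pos, spikes=spikes)


def run_analyze(artifact_dir: str | Path, out_dir: str | Path,
                params: dict | None = None) -> Path:
    """Analyze a simulated (or compatible) artifact directory.

    Stages: ROI assignment, trace extraction, event detection and
    classification, hourly fidelity/summary, decay kinetics, network NAP per
    hour, and (when an MEA recording is present) optical-electrical
    correlation. Each stage's table is written to ``out_dir``.
    """
    artifact_dir = Path(artifact_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or {}
    stack_path = artifact_dir / "stack.tif"
    if not stack_path.exists():
        raise FileNotFoundError(f"no stack.tif in {artifact_dir}")
    stack, schedule, meta = MovieStack.load(stack_path)
    if schedule is None:
        raise ValueError("artifact lacks a stimulation schedule; aborting")

    t0 = time.monotonic()
    rois = assign_rois(stack, schedule,
                       detect_sigma=float(params.get("detect_sigma", 5.0)))
    log.info("analyze: %d ROIs (%.1f s)", rois.n_rois, time.monotonic() - t0)

    traces = extract_traces(stack, rois, schedule)
    traces.save_csv(out_dir / "traces.csv")
    import tifffile
    tifffile.imwrite(out_dir / "roi_labels.tif",
                     rois.label_image.astype(np.uint16))

    events = detect_events(traces, schedule,
                           event_sigma=float(params.get("event_sigma", 5.0)))
    events.to_csv(out_dir / "events.csv", index=False)

    duration_h = float(meta.get("session", {}).get("duration_h",
                       stack.times_s[-1] / 3600.0 if stack.n_frames else 1.0))
    n_windows = max(int(np.ceil(duration_h)), 1)
    windows = [(float(h), float(h + 1)) for h in range(n_windows)]
    fid = fidelity(events, rois.ids, schedule, windows)
    fid.to_csv(out_dir / "fidelity.csv", index=False)
    summary = hourly_summary(events, rois.ids, schedule, windows)
    summary.to_csv(out_dir / "hourly_summary.csv", index=False)

    kinetics = {}
    if rois.n_rois:
        fits = decay_fits_per_stimulus(traces, int(rois.ids[0]),
                                       segment_s=2.0)
        good = [f.t_half_ms for f in fits if f.ok and f.t_half_ms]
        kinetics["decay"] = {
            "roi_id": int(rois.ids[0]),
            "n_fits": len(good),
            "t_half_ms_mean": float(np.mean(good)) if good else None,
            "fits": [f.to_dict() for f in fits],
        }
    (out_dir / "kinetics.json").write_text(json.dumps(kinetics, indent=1))

    nap = nap_by_window(events, rois, windows)
    nap.to_csv(out_dir / "nap.csv", index=False)

    results = {
        "n_rois": int(rois.n_rois),
        "n_events": int(len(events)),
        "event_classes": events["class"].value_counts().to_dict(),
        "hourly_fidelity": summary["mean_fidelity"].tolist(),
        "nap_by_hour": nap["nap"].tolist(),
        "windows_h": windows,
    }

    mea_path = artifact_dir / "mea.csv"
    if mea_path.exists():
        mea = load_mea_csv(mea_path)
        pairs = pair_events(events, mea, rois)
        pairs.to_csv(out_dir / "paired_observations.csv", index=False)
        corr = temporal_correlation(pairs)
        (out_dir / "correlation.json").write_text(
            json.dumps({"temporal": corr.to_dict()}, indent=1))
        results["temporal_r2"] = corr.r2

    pc_path = artifact_dir / "photocurrent.csv"
    if pc_path.exists():
        df = pd.read_csv(pc_path)
        from .simulate import PhotocurrentTrace
        trace = PhotocurrentTrace(time_s=df["t_s"].to_numpy(),
                                  current_pa=df["pA"].to_numpy(),
                                  tau_on_ms=np.nan, tau_off_ms=np.nan,
                                  i_max_pa=float(df["pA"].max()))
        pc_meta = artifact_dir / "photocurrent.json"
        if pc_meta.exists():
            pulse = StimulationSchedule.from_dict(
                json.loads(pc_meta.read_text())["pulse"])
        else:
            pulse = StimulationSchedule.periodic(1, 1.0, pulse_width_ms=100.0)
        fit = fit_photocurrent(trace, pulse)
        results["photocurrent_fit"] = fit.to_dict()

    (out_dir / "summary.json").write_text(
        json.dumps(results, indent=1, default=float))
    write_manifest(out_dir, {"artifact": str(artifact_dir), "params": params},
                   int(meta.get("session", {}).get("seed", 0)))
    log.info("analyze: wrote %s in %.1f s", out_dir, time.monotonic() - t0)
    return out_dir
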