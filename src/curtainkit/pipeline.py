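"""End-to-end orchestration: simulate -> localize -> track -> analyze -> stats.

A single JSON config drives all stages; every run writes a manifest with
the config snapshot, seeds, and SHA-256 hashes of inputs and outputs so
each summary number is traceable.  Stages can be re-run individually
from intermediates.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .simulate import (AcquisitionConfig, DnaTether, MotorParams,
                       make_fixture_suite, render_stack, simulate_motor_path)
from .localize import (SpotDetection, apply_drift, detections_to_frame,
                       estimate_drift, fit_psf, localize_stack)
from .track import (CalibrationMap, Trajectory, calibrate, flow_stop_filter,
                    link_detections, movement_filter, trajectories_to_frame)
from .kinetics import (analyze_trajectory, kinetics_to_frame, pauses_to_frame)
from .cohort import initiation_fraction, summarize_cohort

__all__ = ["run_pipeline", "validate_io", "PipelineError"]

STAGES = ("simulate", "localize", "track", "analyze", "stats")


class PipelineError(ValueError):
    """Config or stage-ordering violation, with the offending field path."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(config: dict) -> list[str]:
    stages = config.get("stages", list(STAGES))
    errors = []
    for s in stages:
        if s not in STAGES:
            errors.append(f"stages: unknown stage '{s}'")
    order = [s for s in STAGES if s in stages]
    if order != stages:
        errors.append("stages: must follow simulate->localize->track->analyze->stats order")
    # each stage needs its producer upstream (or an explicit input file)
    needs = {"localize": ("simulate", "stack"), "track": ("localize", "detections"),
             "analyze": ("track", "trajectories"), "stats": ("analyze", "kinetics")}
    for stage, (producer, key) in needs.items():
        if stage in stages and producer not in stages:
            if not config.get(stage, {}).get(key):
                errors.append(
                    f"{stage}: requires stage '{producer}' or an explicit "
                    f"'{stage}.{key}' input file")
    return errors


def validate_io(files: dict, total_bp: int = 48502) -> dict:
    """Sanity-check pipeline files; returns a report listing violations.

    Checks TIFF readability, required CSV columns, 0-based frame
    indices, and bp coordinates within [0, total_bp].
    """
    violations = []
    for kind, path in files.items():
        p = Path(path)
        if not p.exists():
            violations.append(f"{kind}: missing file {p}")
            continue
        if p.suffix in (".tif", ".tiff"):
            try:
                with tifffile.TiffFile(p) as tf:
                    if len(tf.pages) == 0:
                        violations.append(f"{kind}: empty TIFF {p}")
            except Exception as exc:
                violations.append(f"{kind}: unreadable TIFF {p} ({exc})")
        elif p.suffix == ".csv":
            df = pd.read_csv(p)
            if "frame" in df.columns and (df["frame"] < 0).any():
                violations.append(f"{kind}: negative frame index in {p}")
            if "position_bp" in df.columns:
                bad = df["position_bp"].dropna()
                if ((bad < 0) | (bad > total_bp)).any():
                    violations.append(f"{kind}: position_bp outside [0, {total_bp}] in {p}")
    return {"n_files": len(files), "violations": violations,
            "clean": not violations}


def _cfg_acq(config: dict) -> AcquisitionConfig:
    kw = dict(config.get("acquisition", {}))
    if "image_shape" in kw:
        kw["image_shape"] = tuple(kw["image_shape"])
    if kw.get("flow_stop") is not None:
        kw["flow_stop"] = tuple(kw["flow_stop"])
    if "em_gain_noise" in kw:
        kw["em_gain_noise"] = tuple(kw["em_gain_noise"])
    return AcquisitionConfig(**kw)


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the requested stages and write results plus a manifest.

    Returns the manifest dict.  Determinism contract: the same config
    and seed produce identical summary tables.
    """
    errors = _validate_config(config)
    if errors:
        raise PipelineError("; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    manifest: dict = {
        "version": __version__, "seed": seed, "config": config,
        "started": datetime.datetime.now().isoformat(),
        "stages": {}, "counts": {},
    }

    acq = _cfg_acq(config)
    tether_cfg = dict(config.get("tether", {}))
    if "anchor_px" in tether_cfg:
        tether_cfg["anchor_px"] = tuple(tether_cfg["anchor_px"])
    if "axis_direction" in tether_cfg:
        tether_cfg["axis_direction"] = tuple(tether_cfg["axis_direction"])
    tether = DnaTether(**tether_cfg)
    cal = CalibrationMap(
        anchor_px=(tether.anchor_px[1], tether.anchor_px[0]),  # (x, y)
        axis=(tether.axis_direction[1], tether.axis_direction[0]),
        bp_per_px=tether.bp_per_px, total_bp=tether.total_bp)

    stack = None
    detections: Optional[list[SpotDetection]] = None
    trajs: Optional[list[Trajectory]] = None
    moving = static = None
    kin = None

    if "simulate" in stages:
        sim_cfg = config.get("simulate", {})
        tracks = []
        tethers = []
        for i, m in enumerate(sim_cfg.get("molecules", [])):
            params = MotorParams(**{k: (tuple(map(tuple, v)) if k == "fixed_pauses" and v
                                        else v) for k, v in m.items()})
            row = tether.anchor_px[0] + i * sim_cfg.get("tether_spacing_px", 6.0)
            ti = DnaTether(anchor_px=(row, tether.anchor_px[1]),
                           axis_direction=tether.axis_direction,
                           extension_px=tether.extension_px,
                           total_bp=tether.total_bp)
            tr = simulate_motor_path(params, acq, ti, seed=seed + 101 * i,
                                     molecule_id=i)
            tr.tether_index = i
            tracks.append(tr)
            tethers.append(ti)
        stacks, truth = render_stack(tracks, tethers, acq, seed=seed,
                                     drift=sim_cfg.get("drift"))
        stack = stacks[0]
        stack_path = out / "stack_ch0.tif"
        tifffile.imwrite(stack_path, stack)
        truth.to_csv(out / "ground_truth.csv", index=False)
        manifest["stages"]["simulate"] = {"stack": str(stack_path),
                                          "sha256": _sha256(stack_path)}
        manifest["counts"]["simulated_molecules"] = len(tracks)

    if "localize" in stages:
        loc_cfg = config.get("localize", {})
        if stack is None:
            stack = tifffile.imread(loc_cfg["stack"])
        detections = localize_stack(stack, min_snr=loc_cfg.get("min_snr", 5.0),
                                    window_px=loc_cfg.get("window_px", 9))
        fid_roi = loc_cfg.get("fiducial_roi")  # (row, col, height, width)
        if fid_roi:
            r, c, hh, ww = fid_roi
            fid = [d for d in detections
                   if r <= d.y_px < r + hh and c <= d.x_px < c + ww]
            drift = estimate_drift(fid, n_frames=len(stack),
                                   smooth_window=loc_cfg.get("smooth_window", 1))
            detections = apply_drift(detections, drift)
        det_path = out / "detections.csv"
        detections_to_frame(detections).to_csv(det_path, index=False)
        manifest["stages"]["localize"] = {"detections": str(det_path),
                                          "sha256": _sha256(det_path)}
        manifest["counts"]["detections"] = len(detections)

    if "track" in stages:
        trk_cfg = config.get("track", {})
        if detections is None:
            df = pd.read_csv(trk_cfg["detections"])
            detections = [SpotDetection(**row) for row in df.to_dict("records")]
        trajs = link_detections(detections,
                                max_step_px=trk_cfg.get("max_step_px", 3.0),
                                max_gap_frames=trk_cfg.get("max_gap_frames", 10),
                                frame_interval=acq.frame_interval)
        trajs = [calibrate(t, cal) for t in trajs]
        if acq.flow_stop is not None and trk_cfg.get("use_flow_stop_filter", False):
            trajs, _stuck = flow_stop_filter(
                trajs, acq.flow_stop,
                recoil_threshold_bp=trk_cfg.get("recoil_threshold_bp", 2000.0))
            manifest["counts"]["flow_stop_excluded"] = len(_stuck)
        moving, static = movement_filter(
            trajs, min_displacement_bp=trk_cfg.get("min_displacement_bp", 1000.0),
            exclude_frames=acq.flow_stop)
        traj_path = out / "trajectories.csv"
        trajectories_to_frame(trajs).to_csv(traj_path, index=False)
        manifest["stages"]["track"] = {"trajectories": str(traj_path),
                                       "sha256": _sha256(traj_path)}
        manifest["counts"]["trajectories"] = len(trajs)
        manifest["counts"]["translocating"] = len(moving)
        manifest["counts"]["static"] = len(static)

    if "analyze" in stages:
        an_cfg = config.get("analyze", {})
        if moving is None:
            raise PipelineError("analyze: requires stage 'track' outputs in memory")
        kin = [analyze_trajectory(
                   t, translocating=True,
                   resolution_bp=an_cfg.get("resolution_bp", 500.0),
                   min_pause_duration_s=an_cfg.get("min_pause_duration_s", 30.0),
                   acquisition_duration_s=acq.duration,
                   frame_interval=acq.frame_interval)
               for t in moving]
        kin += [analyze_trajectory(t, translocating=False,
                                   acquisition_duration_s=acq.duration,
                                   frame_interval=acq.frame_interval)
                for t in static]
        kin_path = out / "kinetics.csv"
        kinetics_to_frame(kin).to_csv(kin_path, index=False)
        pauses_to_frame(kin).to_csv(out / "pauses.csv", index=False)
        manifest["stages"]["analyze"] = {"kinetics": str(kin_path),
                                         "sha256": _sha256(kin_path)}

    if "stats" in stages:
        st_cfg = config.get("stats", {})
        if kin is None:
            raise PipelineError("stats: requires stage 'analyze' outputs in memory")
        summary = summarize_cohort(
            st_cfg.get("condition", "default"),
            [k for k in kin if k.translocating],
            n_static=sum(1 for k in kin if not k.translocating),
            horizon_s=st_cfg.get("horizon_s", acq.duration),
            n_boot=st_cfg.get("n_boot", 1000), seed=seed)
        summary_path = out / "summary.json"
        d = asdict(summary)
        summary_path.write_text(json.dumps(d, indent=2, default=float))
        manifest["stages"]["stats"] = {"summary": str(summary_path),
                                       "sha256": _sha256(summary_path)}

    manifest["finished"] = datetime.datetime.now().isoformat()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
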