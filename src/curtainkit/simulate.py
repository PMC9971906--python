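"""Synthetic DNA-curtain image stacks with per-molecule ground truth.

Generates multi-frame two-channel fluorescence movies of point emitters
translocating along flow-stretched DNA tethers: directed motion with
optional pauses and dissociation, quantum-dot style two-state blinking,
stage drift, a flow-stop interval during which tethered molecules recoil
toward the anchor, and EMCCD-like Poisson + Gaussian noise.  Every stack
ships with a sidecar table of true per-frame positions so downstream
localization/tracking/kinetics can be validated against ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

LAMBDA_BP = 48502  # full-length lambda-phage tether

__all__ = [
    "AcquisitionConfig",
    "DnaTether",
    "MotorParams",
    "GroundTruthTrack",
    "simulate_motor_path",
    "render_stack",
    "make_fixture_suite",
    "LAMBDA_BP",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/shutter settings for one movie.

    ``frame_interval`` is the shutter cadence in seconds, ``exposure`` the
    open time per frame.  ``flow_stop`` is an optional ``(start, end)``
    frame window during which buffer flow is halted.  ``em_gain_noise``
    is ``(background mean photons/px, read-noise SD)``.
    """

    frame_interval: float = 2.0
    exposure: float = 0.2
    n_frames: int = 1800
    image_shape: tuple[int, int] = (64, 128)
    pixel_size: float = 0.27  # micrometers / pixel
    channels: int = 1
    flow_stop: Optional[tuple[int, int]] = None
    em_gain_noise: tuple[float, float] = (100.0, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure must not exceed frame_interval")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")
        if self.flow_stop is not None:
            a, b = self.flow_stop
            if not (0 <= a < b <= self.n_frames):
                raise ValueError("flow_stop window must lie within [0, n_frames)")

    @property
    def times(self) -> np.ndarray:
        """Frame midpoint times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @classmethod
    def from_duration(cls, duration_s: float, **kwargs) -> "AcquisitionConfig":
        """Build a config whose frame count covers ``duration_s``."""
        interval = kwargs.pop("frame_interval", 2.0)
        n = int(round(duration_s / interval))
        return cls(frame_interval=interval, n_frames=n, **kwargs)


@dataclass(frozen=True)
class DnaTether:
    """One flow-stretched DNA molecule anchored at ``anchor_px``.

    ``axis_direction`` is the in-plane unit vector pointing from the
    anchor toward the free end; ``extension_px`` is the pixel span of the
    fully extended tether.  Implied scale: ``total_bp / extension_px``
    base pairs per pixel (~485 bp/px at the defaults).
    """

    anchor_px: tuple[float, float] = (5.0, 10.0)  # (row, col)
    axis_direction: tuple[float, float] = (0.0, 1.0)
    extension_px: float = 100.0
    total_bp: int = LAMBDA_BP

    def __post_init__(self) -> None:
        if self.extension_px <= 0:
            raise ValueError("extension_px must be > 0")
        if self.total_bp <= 0:
            raise ValueError("total_bp must be > 0")
        norm = float(np.hypot(*self.axis_direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("axis_direction must be a unit vector")

    @property
    def bp_per_px(self) -> float:
        return self.total_bp / self.extension_px

    def bp_to_px(self, position_bp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map DNA coordinate (bp from anchor) to (row, col) subpixel."""
        d = np.asarray(position_bp, dtype=float) / self.bp_per_px
        r = self.anchor_px[0] + d * self.axis_direction[0]
        c = self.anchor_px[1] + d * self.axis_direction[1]
        return r, c


@dataclass(frozen=True)
class MotorParams:
    """Behavioral parameters for one simulated molecule.

    Pauses arrive at ``pause_rate`` (per second of motile time) and last
    Exp(``pause_duration_mean``); ``fixed_pauses`` bypasses the random
    pause process with explicit ``(t_start, duration)`` events.
    ``max_travel_bp`` forces dissociation once that net distance has been
    covered (used to simulate cohorts with prescribed processivities).
    Blinking is a two-state telegraph process with the given rates.
    """

    initial_position_bp: float = 1000.0
    velocity_bp_s: float = 0.0
    velocity_noise_sd: float = 0.0  # bp / sqrt(s) Brownian jitter
    pause_rate: float = 0.0
    pause_duration_mean: float = 60.0
    dissociation_rate: float = 0.0
    initiates: bool = True
    blink_on_rate: float = 0.0   # dark -> emitting (1/s)
    blink_off_rate: float = 0.0  # emitting -> dark (1/s)
    amplitude_photons: float = 2000.0
    psf_sigma_px: float = 1.1
    fixed_pauses: Optional[tuple[tuple[float, float], ...]] = None
    max_travel_bp: Optional[float] = None
    tethered: bool = True  # False = surface-stuck decoy (no recoil)

    def __post_init__(self) -> None:
        for name in ("pause_rate", "dissociation_rate", "blink_on_rate",
                     "blink_off_rate", "pause_duration_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.amplitude_photons < 0:
            raise ValueError("amplitude_photons must be >= 0")


@dataclass
class GroundTruthTrack:
    """True per-frame state of one simulated molecule (test oracle)."""

    molecule_id: int
    channel: int
    position_bp: np.ndarray      # NaN while unbound
    emitting: np.ndarray         # bool per frame
    bound: np.ndarray            # bool per frame
    pauses: list[tuple[float, float]] = field(default_factory=list)
    dissociation_time: Optional[float] = None  # None = censored at movie end
    params: Optional[MotorParams] = None
    tether_index: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.position_bp)

    def net_displacement_bp(self) -> float:
        """Actual distance covered from start to farthest excursion."""
        p = self.position_bp[self.bound]
        if p.size == 0:
            return 0.0
        return float(np.max(np.abs(p - p[0])))

    def bound_lifetime_s(self, frame_interval: float) -> float:
        n_bound = int(np.sum(self.bound))
        return n_bound * frame_interval


def _draw_pause_schedule(params: MotorParams, horizon: float,
                         rng: np.random.Generator) -> list[tuple[float, float]]:
    """Exponentially spaced pauses over the motile clock, as (start, end)."""
    if params.fixed_pauses is not None:
        return [(t0, t0 + d) for t0, d in params.fixed_pauses]
    if params.pause_rate <= 0:
        return []
    pauses = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / params.pause_rate)
        if t >= horizon:
            break
        dur = rng.exponential(params.pause_duration_mean)
        pauses.append((t, t + dur))
        t += dur
    return pauses


def simulate_motor_path(params: MotorParams, acq: AcquisitionConfig,
                        tether: DnaTether, seed: int = 0,
                        molecule_id: int = 0, channel: int = 0) -> GroundTruthTrack:
    """Simulate one molecule's piecewise trajectory along the tether.

    Constant-velocity motion interrupted by zero-velocity pauses, with
    optional exponential dissociation, Brownian positional jitter, and
    per-frame telegraph blinking.  The path is clipped to
    ``[0, total_bp]``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    times = acq.times
    n = acq.n_frames
    dt = acq.frame_interval

    pauses = _draw_pause_schedule(params, acq.duration, rng)

    # dissociation clock (exponential), independent of pausing
    diss_t: Optional[float] = None
    if params.dissociation_rate > 0:
        cand = rng.exponential(1.0 / params.dissociation_rate)
        if cand < acq.duration:
            diss_t = float(cand)

    def _paused(t: float) -> bool:
        return any(a <= t < b for a, b in pauses)

    # integrate velocity over frame intervals
    pos = np.empty(n)
    pos[0] = params.initial_position_bp
    v = params.velocity_bp_s if params.initiates else 0.0
    travelled = 0.0
    travel_diss_t: Optional[float] = None
    for i in range(1, n):
        t0, t1 = times[i - 1], times[i]
        # fraction of [t0, t1) spent motile (subtract pause overlap)
        overlap = sum(max(0.0, min(b, t1) - max(a, t0)) for a, b in pauses)
        motile = dt - overlap
        step = v * motile
        pos[i] = pos[i - 1] + step
        if params.max_travel_bp is not None:
            travelled += abs(step)
            if travel_diss_t is None and travelled >= params.max_travel_bp:
                travel_diss_t = float(t1)
    if params.velocity_noise_sd > 0:
        jitter = rng.normal(0.0, params.velocity_noise_sd * np.sqrt(dt), size=n)
        jitter[0] = 0.0
        pos = pos + np.cumsum(jitter)
    pos = np.clip(pos, 0.0, tether.total_bp)

    if travel_diss_t is not None and (diss_t is None or travel_diss_t < diss_t):
        diss_t = travel_diss_t

    bound = np.ones(n, dtype=bool)
    if diss_t is not None:
        bound[times >= diss_t] = False
    pos = np.where(bound, pos, np.nan)

    # two-state blinking telegraph sampled at frame boundaries
    emitting = np.ones(n, dtype=bool)
    if params.blink_off_rate > 0 or params.blink_on_rate > 0:
        # exact two-state CTMC transition probabilities over one interval
        s = params.blink_on_rate + params.blink_off_rate
        decay = 1.0 - np.exp(-s * dt)
        p_off = params.blink_off_rate / s * decay  # emitting -> dark
        p_on = params.blink_on_rate / s * decay    # dark -> emitting
        u = rng.random(n)
        state = True
        for i in range(n):
            emitting[i] = state
            if state:
                state = u[i] >= p_off
            else:
                state = u[i] < p_on
    emitting &= bound

    # keep only pauses that fall inside the bound lifetime
    end_t = diss_t if diss_t is not None else acq.duration
    kept = [(a, min(b, end_t)) for a, b in pauses if a < end_t and b > a]

    return GroundTruthTrack(
        molecule_id=molecule_id, channel=channel, position_bp=pos,
        emitting=emitting, bound=bound, pauses=kept,
        dissociation_time=diss_t, params=params, tether_index=0,
    )


def _integrated_gaussian_stamp(r0: float, c0: float, amplitude: float,
                               sigma: float, rows: np.ndarray,
                               cols: np.ndarray) -> np.ndarray:
    """Pixel-integrated symmetric 2D Gaussian (total volume = amplitude)."""
    s = sigma * np.sqrt(2.0)
    fr = 0.5 * (erf((rows + 0.5 - r0) / s) - erf((rows - 0.5 - r0) / s))
    fc = 0.5 * (erf((cols + 0.5 - c0) / s) - erf((cols - 0.5 - c0) / s))
    return amplitude * np.outer(fr, fc)


def _resolve_drift(drift, n_frames: int) -> np.ndarray:
    """Accept None, a (d_row, d_col) per-frame rate, or an (n, 2) array."""
    if drift is None:
        return np.zeros((n_frames, 2))
    arr = np.asarray(drift, dtype=float)
    if arr.shape == (2,):
        return np.outer(np.arange(n_frames), arr)
    if arr.shape != (n_frames, 2):
        raise ValueError("drift must be (d_row, d_col) per frame or (n_frames, 2)")
    return arr


def render_stack(tracks: Sequence[GroundTruthTrack],
                 tethers: Sequence[DnaTether],
                 acq: AcquisitionConfig, seed: int = 0,
                 drift=None, noise: bool = True,
                 recoil_factor: float = 0.8,
                 stamp_halfwidth: int = 7):
    """Render tracks into per-channel image stacks plus a ground-truth table.

    Each emitting molecule contributes a pixel-integrated 2D Gaussian at
    its mapped subpixel location.  During the flow-stop window, tethered
    molecules are drawn ``recoil_factor`` of the way back toward their
    anchor; surface-stuck decoys stay put.  Shot noise is Poisson on
    signal+background, plus Gaussian read noise.

    Returns ``(stacks, truth)`` where ``stacks`` is a list of
    ``(n_frames, rows, cols)`` uint16 arrays (one per channel) and
    ``truth`` is a tidy DataFrame of true per-frame states.
    """
    rng = np.random.default_rng(seed)
    n = acq.n_frames
    h, w = acq.image_shape
    bg, read_sd = acq.em_gain_noise
    drift_arr = _resolve_drift(drift, n)

    for tr in tracks:
        if tr.params is not None and tr.params.amplitude_photons < 0:
            raise ValueError("negative amplitude")

    signal = [np.zeros((n, h, w), dtype=float) for _ in range(acq.channels)]
    truth_rows = []
    warned = False

    fs = acq.flow_stop
    for tr in tracks:
        tether = tethers[tr.tether_index]
        p = tr.params or MotorParams()
        amp, sig = p.amplitude_photons, p.psf_sigma_px
        pos = tr.position_bp.copy()
        if fs is not None and p.tethered:
            in_stop = np.zeros(n, dtype=bool)
            in_stop[fs[0]:fs[1]] = True
            pos = np.where(in_stop & tr.bound, pos * (1.0 - recoil_factor), pos)
        rr, cc = tether.bp_to_px(np.nan_to_num(pos))
        rr = rr + drift_arr[:, 0]
        cc = cc + drift_arr[:, 1]
        for i in range(n):
            emit = bool(tr.emitting[i]) and bool(tr.bound[i]) and amp > 0
            truth_rows.append((tr.molecule_id, tr.channel, i, i * acq.frame_interval,
                               tr.position_bp[i], bool(tr.emitting[i]),
                               bool(tr.bound[i]), rr[i] if tr.bound[i] else np.nan,
                               cc[i] if tr.bound[i] else np.nan))
            if not emit:
                continue
            r0, c0 = rr[i], cc[i]
            if not (0 <= r0 < h and 0 <= c0 < w):
                if not warned:
                    warnings.warn("emitter outside frame; clipped", stacklevel=2)
                    warned = True
                r0 = min(max(r0, 0.0), h - 1.0)
                c0 = min(max(c0, 0.0), w - 1.0)
            ri = int(round(r0))
            ci = int(round(c0))
            r_lo, r_hi = max(0, ri - stamp_halfwidth), min(h, ri + stamp_halfwidth + 1)
            c_lo, c_hi = max(0, ci - stamp_halfwidth), min(w, ci + stamp_halfwidth + 1)
            stamp = _integrated_gaussian_stamp(
                r0, c0, amp, sig, np.arange(r_lo, r_hi), np.arange(c_lo, c_hi))
            signal[tr.channel][i, r_lo:r_hi, c_lo:c_hi] += stamp

    stacks = []
    for ch in range(acq.channels):
        img = signal[ch] + bg
        if noise:
            img = rng.poisson(img).astype(float)
            img += rng.normal(0.0, read_sd, size=img.shape)
        img = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        stacks.append(img)

    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_id", "channel", "frame", "time_s", "true_position_bp",
                 "emitting", "bound", "true_row_px", "true_col_px"],
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# fixture battery

def _default_fixture_specs() -> dict[str, MotorParams]:
    return {
        "stationary_fiducial": MotorParams(
            initial_position_bp=0.0, velocity_bp_s=0.0, tethered=False,
            amplitude_photons=3000.0),
        "slow_mover": MotorParams(
            initial_position_bp=2000.0, velocity_bp_s=9.0),
        "fast_mover": MotorParams(
            initial_position_bp=2000.0, velocity_bp_s=18.0),
        "pausing_mover": MotorParams(
            initial_position_bp=2000.0, velocity_bp_s=15.0,
            fixed_pauses=((120.0, 60.0),)),
        "blinking_mover": MotorParams(
            initial_position_bp=2000.0, velocity_bp_s=12.0,
            blink_on_rate=0.4, blink_off_rate=0.1),
        "surface_stuck_decoy": MotorParams(
            initial_position_bp=20000.0, velocity_bp_s=0.0, tethered=False),
        "coloc_pair_a": MotorParams(
            initial_position_bp=5000.0, velocity_bp_s=10.0),
        "coloc_pair_b": MotorParams(
            initial_position_bp=5000.0, velocity_bp_s=10.0),
    }


def make_fixture_suite(out_dir, acq: Optional[AcquisitionConfig] = None,
                       seed: int = 0) -> dict:
    """Write the standard validation battery to ``out_dir``.

    One two-channel stack containing: a stationary fiducial, slow and
    fast movers, a pausing mover (single 60 s pause), a blinking mover,
    a surface-stuck decoy, and a colocalized two-channel pair.  Output:
    per-channel TIFFs, a ground-truth CSV, and a config JSON.  Fully
    deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if acq is None:
        acq = AcquisitionConfig(n_frames=300, image_shape=(60, 128), channels=2,
                                flow_stop=(10, 25), rng_seed=seed)

    specs = _default_fixture_specs()
    tracks, tethers, names = [], [], []
    for k, (name, params) in enumerate(specs.items()):
        tether = DnaTether(anchor_px=(6.0 + 6.0 * k, 10.0))
        channel = 1 if name == "coloc_pair_b" else 0
        if name == "coloc_pair_b":  # share the pair's tether
            tether = tethers[-1]
        track = simulate_motor_path(params, acq, tether, seed=seed + 17 * k,
                                    molecule_id=k, channel=channel)
        track.tether_index = len(tethers) - 1 if name == "coloc_pair_b" else len(tethers)
        if name != "coloc_pair_b":
            tethers.append(tether)
        tracks.append(track)
        names.append(name)

    stacks, truth = render_stack(tracks, tethers, acq, seed=seed)
    truth["fixture"] = truth["molecule_id"].map(dict(enumerate(names)))

    paths = {}
    for ch, stack in enumerate(stacks):
        p = out / f"stack_ch{ch}.tif"
        tifffile.imwrite(p, stack)
        paths[f"stack_ch{ch}"] = str(p)
    truth_path = out / "ground_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.6f")
    paths["ground_truth"] = str(truth_path)

    cfg = {
        "seed": seed,
        "acquisition": asdict(acq),
        "fixtures": {name: asdict(params) for name, params in specs.items()},
        "tethers": [asdict(t) for t in tethers],
    }
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(cfg, indent=2, default=list))
    paths["config"] = str(cfg_path)
    return {"paths": paths, "tracks": tracks, "tethers": tethers,
            "names": names, "acq": acq, "truth": truth}
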