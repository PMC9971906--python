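"""Per-trajectory resection kinetics.

Velocity is the OLS slope of position vs time over the motile span (a
single line per molecule, pauses included by default).  Processivity is
the net distance from motion start to the farthest excursion.  Pauses
are intervals of >= 30 s with no net movement beyond the ~500 bp spatial
resolution, found with a sliding-window local-velocity detector.  Bound
lifetimes feed a single-exponential survival fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .track import Trajectory

__all__ = [
    "PauseEvent",
    "TrajectoryKinetics",
    "SurvivalFit",
    "compute_velocity",
    "compute_processivity",
    "motion_start_index",
    "detect_pauses",
    "pause_summary",
    "fit_survival",
    "dissociation_fraction",
    "analyze_trajectory",
]

DEFAULT_RESOLUTION_BP = 500.0
DEFAULT_MIN_PAUSE_S = 30.0
# pause threshold relative to the motile velocity: windows slower than
# this fraction of v are pause candidates.  0.6 keeps the candidate-run
# edges within ~2 s of the true boundaries for clean piecewise paths
# while leaving headroom above window-slope noise for slow movers.
_REL_THRESHOLD = 0.6


@dataclass
class PauseEvent:
    t_start: float
    t_end: float
    position_bp: float
    prepause_velocity: Optional[float] = None
    postpause_velocity: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TrajectoryKinetics:
    molecule_id: int
    velocity_bp_s: float
    velocity_stderr: float
    processivity_kb: float
    pauses: list[PauseEvent] = field(default_factory=list)
    bound_lifetime_s: float = 0.0
    dissociated_within_horizon: bool = False
    translocating: bool = True
    short_trace: bool = False

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)


@dataclass
class SurvivalFit:
    """Single-exponential dwell-time fit: S(t) = exp(-k t)."""

    k: float
    method: str
    n: int
    n_censored: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate must be positive")

    @property
    def half_life_s(self) -> float:
        return float(np.log(2.0) / self.k)


def _ols(t: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error; stderr is 0 for exactly collinear data."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(t)
    tbar, pbar = t.mean(), p.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        return 0.0, np.inf
    slope = float(np.sum((t - tbar) * (p - pbar)) / sxx)
    resid = p - pbar - slope * (t - tbar)
    if n > 2:
        se = float(np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx))
    else:
        se = 0.0
    return slope, se


def motion_start_index(traj: Trajectory,
                       resolution_bp: float = DEFAULT_RESOLUTION_BP) -> int:
    """Start of sustained motion: the breakpoint of a two-segment
    (initial plateau + line) least-squares fit.

    The breakpoint is searched up to the last frame at which the
    displacement from the start has not yet permanently exceeded the
    spatial resolution; a molecule that moves from frame 0 gets start
    index 0, so no run-in distance is lost.
    """
    p = traj.position_bp
    t = traj.times_s
    n = len(p)
    disp = np.abs(p - p[0])
    above = disp > resolution_bp
    if not above.any() or n < 5:
        return 0
    below = np.where(~above)[0]
    b_max = min(int(below[-1]) + 1, n - 3)

    def sse(b: int) -> float:
        s = 0.0
        if b > 0:
            plateau = p[:b + 1]
            s += float(np.sum((plateau - plateau.mean()) ** 2))
        tt, pp = t[b:], p[b:]
        slope, _ = _ols(tt, pp)
        resid = pp - pp.mean() - slope * (tt - tt.mean())
        return s + float(np.sum(resid ** 2))

    costs = [sse(b) for b in range(0, b_max + 1)]
    return int(np.argmin(costs))


def _motile_span(traj: Trajectory,
                 resolution_bp: float = DEFAULT_RESOLUTION_BP) -> tuple[int, int]:
    """(start, end) indices of net movement: motion start to the first
    frame at which the maximum excursion is reached."""
    p = traj.position_bp
    i0 = motion_start_index(traj, resolution_bp)
    disp = np.abs(p - p[i0])
    i1 = int(np.argmax(disp))
    if i1 <= i0:
        i1 = len(p) - 1
    return i0, i1


def compute_velocity(traj: Trajectory, exclude_pauses: bool = False,
                     resolution_bp: float = DEFAULT_RESOLUTION_BP,
                     min_points: int = 5,
                     pauses: Optional[Sequence[PauseEvent]] = None,
                     ) -> tuple[float, float]:
    """OLS slope (bp/s) of position vs time over the motile span.

    Positive = away from the tethered end.  With ``exclude_pauses``,
    frames inside detected pause intervals are dropped before fitting
    (diagnostic mode; the default single-line fit includes them).
    """
    if traj.position_bp is None:
        raise ValueError("calibrated trajectory required")
    if traj.n_points < min_points:
        raise ValueError(f"need at least {min_points} points")
    i0, i1 = _motile_span(traj, resolution_bp)
    t = traj.times_s[i0:i1 + 1]
    p = traj.position_bp[i0:i1 + 1]
    if exclude_pauses:
        if pauses is None:
            pauses = detect_pauses(traj, resolution_bp=resolution_bp)
        keep = np.ones(len(t), dtype=bool)
        for ev in pauses:
            keep &= ~((t >= ev.t_start) & (t <= ev.t_end))
        if keep.sum() >= min_points:
            # motile segments are offset by the pauses; fit each one
            # separately and average slopes weighted by segment span
            idx = np.where(keep)[0]
            segments = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
            slopes, ses, weights = [], [], []
            for seg in segments:
                if len(seg) < 3:
                    continue
                s, e = _ols(t[seg], p[seg])
                slopes.append(s)
                ses.append(e)
                weights.append(t[seg[-1]] - t[seg[0]])
            if slopes:
                w = np.asarray(weights) / np.sum(weights)
                return (float(np.sum(w * slopes)),
                        float(np.sqrt(np.sum((w * np.asarray(ses)) ** 2))))
    if len(t) < 2:
        return 0.0, 0.0
    return _ols(t, p)


def compute_processivity(traj: Trajectory,
                         resolution_bp: float = DEFAULT_RESOLUTION_BP,
                         mode: str = "net") -> float:
    """Distance traveled along DNA, in kb.

    ``net`` (default): |position at maximum excursion - position at
    motion start|.  ``path``: total absolute path length over the motile
    span (alternative reading of "distance traveled").
    """
    if traj.position_bp is None:
        raise ValueError("calibrated trajectory required")
    p = traj.position_bp
    i0 = motion_start_index(traj, resolution_bp)
    if mode == "net":
        dist = float(np.max(np.abs(p[i0:] - p[i0])))
    elif mode == "path":
        dist = float(np.sum(np.abs(np.diff(p[i0:]))))
    else:
        raise ValueError("mode must be 'net' or 'path'")
    return dist / 1000.0


def detect_pauses(traj: Trajectory,
                  resolution_bp: float = DEFAULT_RESOLUTION_BP,
                  min_pause_duration_s: float = DEFAULT_MIN_PAUSE_S,
                  ) -> list[PauseEvent]:
    """Sliding-window pause detector.

    A window of ``min_pause_duration_s`` is slid along the trace and its
    local OLS velocity computed; window centers where |local velocity|
    falls below the pause threshold are merged into candidate runs, and
    runs lasting >= ``min_pause_duration_s`` become events.  The
    threshold is the smaller of resolution/duration (the assay's
    detectability limit, ~17 bp/s at defaults) and half the molecule's
    own motile velocity, so that genuinely slow-but-steady movers are
    not wall-to-wall "paused".  Runs in two passes: pause intervals from
    the first pass are excluded when re-estimating the motile velocity
    for the second.

    Traces shorter than one window return no events.
    """
    if traj.position_bp is None:
        raise ValueError("calibrated trajectory required")
    t = traj.times_s
    p = traj.position_bp
    if traj.duration_s < min_pause_duration_s or traj.n_points < 4:
        return []

    dt = float(np.median(np.diff(t)))
    w = max(3, int(round(min_pause_duration_s / dt)))
    if w >= traj.n_points:
        return []

    limit = resolution_bp / min_pause_duration_s

    def window_speeds() -> tuple[np.ndarray, np.ndarray]:
        centers, speeds = [], []
        for i in range(traj.n_points - w + 1):
            sl = slice(i, i + w)
            slope, _ = _ols(t[sl], p[sl])
            centers.append(0.5 * (t[i] + t[i + w - 1]))
            speeds.append(abs(slope))
        return np.array(centers), np.array(speeds)

    centers, speeds = window_speeds()

    def find_events(threshold: float) -> list[tuple[float, float]]:
        # <= so that a window centered exactly on a pause boundary (local
        # speed exactly v/2) is marked, making event edges land on the
        # true boundaries for clean piecewise paths
        below = speeds <= threshold + 1e-9
        # close single/double-window breaks: one noisy window should not
        # split an otherwise contiguous pause run
        for i in range(1, len(below) - 2):
            if below[i - 1] and not below[i] and (below[i + 1] or below[i + 2]):
                below[i] = True
        events = []
        i = 0
        while i < len(below):
            if below[i]:
                j = i
                while j + 1 < len(below) and below[j + 1]:
                    j += 1
                t0, t1 = centers[i], centers[j]
                if t1 - t0 + dt >= min_pause_duration_s:
                    events.append((t0, t1))
                i = j + 1
            else:
                i += 1
        return events

    def motile_velocity(events: list[tuple[float, float]]) -> float:
        # exclude a half-window margin around each event, then fit each
        # remaining contiguous motile segment separately (segments are
        # offset from one another by the pauses) and average the slopes
        # weighted by segment span
        margin = 0.5 * min_pause_duration_s
        keep = np.ones(traj.n_points, dtype=bool)
        for a, b in events:
            keep &= ~((t >= a - margin) & (t <= b + margin))
        if keep.sum() < 3:
            return abs(_ols(t, p)[0])
        idx = np.where(keep)[0]
        breaks = np.where(np.diff(idx) > 1)[0]
        segments = np.split(idx, breaks + 1)
        slopes, weights = [], []
        for seg in segments:
            if len(seg) < 3:
                continue
            slopes.append(abs(_ols(t[seg], p[seg])[0]))
            weights.append(t[seg[-1]] - t[seg[0]])
        if not slopes:
            return abs(_ols(t[keep], p[keep])[0])
        return float(np.average(slopes, weights=weights))

    # pass 1: provisional threshold from the global slope
    v0 = abs(_ols(t, p)[0])
    thr = min(limit, _REL_THRESHOLD * v0) if v0 > 0 else limit
    events = find_events(thr)
    # pass 2: re-estimate motile velocity excluding provisional pauses
    v1 = motile_velocity(events)
    thr = min(limit, _REL_THRESHOLD * v1) if v1 > 0 else limit
    events = find_events(thr)

    out = []
    for t0, t1 in events:
        inside = (t >= t0) & (t <= t1)
        pos = float(np.median(p[inside])) if inside.any() else float("nan")
        pre_mask = (t < t0) & (t >= t0 - 2 * min_pause_duration_s)
        post_mask = (t > t1) & (t <= t1 + 2 * min_pause_duration_s)
        pre = _ols(t[pre_mask], p[pre_mask])[0] if pre_mask.sum() >= 3 else None
        post = _ols(t[post_mask], p[post_mask])[0] if post_mask.sum() >= 3 else None
        out.append(PauseEvent(t_start=float(t0), t_end=float(t1),
                              position_bp=pos, prepause_velocity=pre,
                              postpause_velocity=post))
    return out


def pause_summary(kinetics: Sequence[TrajectoryKinetics]) -> dict:
    """Pause-count fractions over translocating molecules.

    Returns fractions of molecules with no pause, >= 1 pause and
    >= 2 pauses, plus the >= 2 fraction *among paused molecules* and all
    underlying counts (the style the assay reports as "n = x/y").
    """
    moving = [k for k in kinetics if k.translocating]
    if not moving:
        raise ValueError("no translocating trajectories")
    n = len(moving)
    n1 = sum(1 for k in moving if k.n_pauses >= 1)
    n2 = sum(1 for k in moving if k.n_pauses >= 2)
    return {
        "n_translocating": n,
        "n_paused": n1,
        "n_multipause": n2,
        "frac_no_pause": (n - n1) / n,
        "frac_paused": n1 / n,
        "frac_multipause": n2 / n,
        "frac_multipause_among_paused": (n2 / n1) if n1 else 0.0,
    }


def empirical_survival(lifetimes: np.ndarray,
                       censored: Optional[np.ndarray] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier survival curve S(t) at the observed event times."""
    lifetimes = np.asarray(lifetimes, dtype=float)
    if censored is None:
        censored = np.zeros(len(lifetimes), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    order = np.argsort(lifetimes, kind="stable")
    t_sorted = lifetimes[order]
    c_sorted = censored[order]
    at_risk = len(lifetimes)
    times, surv = [], []
    s = 1.0
    for t_val, cens in zip(t_sorted, c_sorted):
        if not cens:
            s *= (at_risk - 1) / at_risk
            times.append(t_val)
            surv.append(s)
        at_risk -= 1
    return np.array(times), np.array(surv)


def fit_survival(bound_lifetimes: Sequence[float],
                 censored: Optional[Sequence[bool]] = None,
                 method: str = "nls", min_n: int = 10) -> SurvivalFit:
    """Fit S(t) = exp(-k t) to the empirical survival curve.

    ``nls`` (default): least squares on S(t) directly.  ``loglinear``:
    least squares of ln S on t through the origin, using S > 0 points.
    ``mle``: censoring-aware exponential maximum likelihood
    (k = events / total observed time).
    """
    lifetimes = np.asarray(bound_lifetimes, dtype=float)
    if len(lifetimes) < min_n:
        raise ValueError(f"need at least {min_n} lifetimes")
    cens = (np.zeros(len(lifetimes), dtype=bool) if censored is None
            else np.asarray(censored, dtype=bool))
    n_events = int((~cens).sum())
    if n_events == 0:
        raise ValueError("all lifetimes are censored")

    if method == "mle":
        k = n_events / float(lifetimes.sum())
        return SurvivalFit(k=k, method=method, n=len(lifetimes),
                           n_censored=int(cens.sum()))

    times, surv = empirical_survival(lifetimes, cens)
    if method == "loglinear":
        pos = surv > 0
        tt, ss = times[pos], surv[pos]
        k = float(-np.sum(tt * np.log(ss)) / np.sum(tt ** 2))
    elif method == "nls":
        k0 = np.log(2.0) / max(np.median(lifetimes), 1e-9)
        res = optimize.least_squares(
            lambda q: np.exp(-q[0] * times) - surv, x0=[k0],
            bounds=([1e-12], [np.inf]))
        k = float(res.x[0])
    else:
        raise ValueError("method must be 'nls', 'loglinear' or 'mle'")
    return SurvivalFit(k=k, method=method, n=len(lifetimes),
                       n_censored=int(cens.sum()))


def dissociation_fraction(kinetics: Sequence[TrajectoryKinetics],
                          horizon_s: float = 1800.0, n_boot: int = 1000,
                          seed: int = 0) -> tuple[float, float]:
    """Fraction of molecules that dissociated before ``horizon_s``,
    with a bootstrap SD (molecule-level resampling)."""
    if not kinetics:
        raise ValueError("empty input")
    flags = np.array([k.bound_lifetime_s < horizon_s and k.dissociated_within_horizon
                      for k in kinetics], dtype=float)
    frac = float(flags.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(flags), size=(n_boot, len(flags)))
    sd = float(flags[idx].mean(axis=1).std(ddof=1))
    return frac, sd


def analyze_trajectory(traj: Trajectory, translocating: bool = True,
                       resolution_bp: float = DEFAULT_RESOLUTION_BP,
                       min_pause_duration_s: float = DEFAULT_MIN_PAUSE_S,
                       acquisition_duration_s: Optional[float] = None,
                       frame_interval: float = 2.0) -> TrajectoryKinetics:
    """Full per-molecule kinetics: velocity, processivity, pauses, lifetime."""
    lifetime = traj.duration_s + frame_interval
    dissociated = True
    if acquisition_duration_s is not None:
        lifetime = min(lifetime, acquisition_duration_s)
        # still present in the last frame -> right-censored
        dissociated = traj.times_s[-1] + 2 * frame_interval < acquisition_duration_s
    if not translocating or traj.n_points < 5:
        return TrajectoryKinetics(
            molecule_id=traj.molecule_id, velocity_bp_s=0.0, velocity_stderr=0.0,
            processivity_kb=0.0, pauses=[], bound_lifetime_s=lifetime,
            dissociated_within_horizon=dissociated, translocating=False,
            short_trace=traj.duration_s < min_pause_duration_s)
    v, se = compute_velocity(traj, resolution_bp=resolution_bp)
    proc = compute_processivity(traj, resolution_bp=resolution_bp)
    pauses = detect_pauses(traj, resolution_bp=resolution_bp,
                           min_pause_duration_s=min_pause_duration_s)
    return TrajectoryKinetics(
        molecule_id=traj.molecule_id, velocity_bp_s=v, velocity_stderr=se,
        processivity_kb=proc, pauses=pauses, bound_lifetime_s=lifetime,
        dissociated_within_horizon=dissociated, translocating=True,
        short_trace=traj.duration_s < min_pause_duration_s)


def kinetics_to_frame(kinetics: Sequence[TrajectoryKinetics]) -> pd.DataFrame:
    rows = [(k.molecule_id, k.velocity_bp_s, k.velocity_stderr, k.processivity_kb,
             k.n_pauses, k.bound_lifetime_s, k.dissociated_within_horizon,
             k.translocating) for k in kinetics]
    return pd.DataFrame(rows, columns=[
        "molecule_id", "velocity_bp_s", "velocity_stderr", "processivity_kb",
        "n_pauses", "bound_lifetime_s", "dissociated_within_horizon",
        "translocating"])


def pauses_to_frame(kinetics: Sequence[TrajectoryKinetics]) -> pd.DataFrame:
    rows = []
    for k in kinetics:
        for ev in k.pauses:
            rows.append((k.molecule_id, ev.t_start, ev.t_end, ev.duration,
                         ev.position_bp, ev.prepause_velocity,
                         ev.postpause_velocity))
    return pd.DataFrame(rows, columns=[
        "molecule_id", "t_start", "t_end", "duration_s", "position_bp",
        "prepause_velocity", "postpause_velocity"])
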