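"""Condition-level statistics for single-molecule cohorts.

Initiation/colocalization fractions with bootstrap SDs, two-sample
comparisons with figure-legend significance stars, fold changes, and the
GC-content vs pause-position association.  Fractions are always reported
with their raw counts (the "n = x/y" style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .track import Trajectory
from .kinetics import TrajectoryKinetics

__all__ = [
    "CohortSummary",
    "ColocalizationResult",
    "initiation_fraction",
    "bootstrap_fraction",
    "colocalize",
    "compare_groups",
    "significance_stars",
    "fold_change",
    "gc_profile",
    "pause_gc_association",
    "summarize_cohort",
]


@dataclass
class CohortSummary:
    """Per-condition aggregates in the form the figures report."""

    condition: str
    n_molecules: int
    velocity_mean: float
    velocity_sd: float
    velocity_median: float
    velocity_iqr: tuple[float, float]
    processivity_mean: float
    processivity_sd: float
    processivity_median: float
    processivity_iqr: tuple[float, float]
    initiation_fraction: float
    initiation_sd: float
    frac_paused: float
    dissociation_fraction: float


@dataclass
class ColocalizationResult:
    n_a: int
    n_colocalized: int
    bootstrap_sd: float
    threshold_bp: float
    min_overlap_frames: int

    def __post_init__(self) -> None:
        if self.n_colocalized > self.n_a:
            raise ValueError("colocalized count exceeds total")

    @property
    def fraction(self) -> float:
        return self.n_colocalized / self.n_a if self.n_a else float("nan")


def bootstrap_fraction(flags: Sequence[bool], n_boot: int = 1000,
                       seed: int = 0) -> tuple[float, float]:
    """Fraction of true flags and its bootstrap SD.

    Molecules are resampled with replacement ``n_boot`` times; the SD of
    the resampled fractions estimates the error bar (converges to the
    binomial SE for large n_boot).
    """
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("need at least one flag")
    frac = float(flags.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    sd = float(flags[idx].mean(axis=1).std(ddof=1))
    return frac, sd


def initiation_fraction(translocating: Sequence, static: Sequence,
                        n_boot: int = 1000, seed: int = 0) -> dict:
    """Fraction of end-bound molecules that initiated long-range
    translocation, with bootstrap SD and the underlying counts."""
    n_moving = len(translocating)
    n_total = n_moving + len(static)
    if n_total == 0:
        raise ValueError("empty denominator: no bound molecules")
    flags = np.concatenate([np.ones(n_moving), np.zeros(n_total - n_moving)])
    frac, sd = bootstrap_fraction(flags, n_boot=n_boot, seed=seed)
    return {"fraction": frac, "sd": sd, "n_initiated": n_moving, "n_total": n_total}


def fraction_from_counts(numerator: int, denominator: int) -> float:
    """Worked-example helper: a fraction from printed x/y counts via the
    same bootstrap_fraction code path (SD discarded)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator out of range")
    flags = np.concatenate([np.ones(numerator), np.zeros(denominator - numerator)])
    frac, _ = bootstrap_fraction(flags, n_boot=2, seed=0)
    return frac


def colocalize(trajs_a: Sequence[Trajectory], trajs_b: Sequence[Trajectory],
               threshold_bp: float = 1000.0, min_overlap_frames: int = 5,
               n_boot: int = 1000, seed: int = 0) -> ColocalizationResult:
    """Score each A-molecule as colocalized if some B-molecule stays
    within ``threshold_bp`` along the tether for at least
    ``min_overlap_frames`` simultaneous frames.

    Directional: fraction of A near B generally differs from B near A.
    Both channels must be drift-corrected and registered beforehand.
    Trajectories carrying a ``tether_id`` are only compared against
    partners on the same tether; untagged trajectories compare globally.
    """
    if not trajs_a:
        raise ValueError("channel A is empty")
    flags = []
    for ta in trajs_a:
        if ta.position_bp is None:
            raise ValueError("calibrated trajectories required")
        hit = False
        fa = {int(f): float(p) for f, p in zip(ta.frames, ta.position_bp)}
        candidates = [tb for tb in trajs_b
                      if ta.tether_id is None or tb.tether_id is None
                      or ta.tether_id == tb.tether_id]
        for tb in candidates:
            if tb.position_bp is None:
                raise ValueError("calibrated trajectories required")
            n_close = 0
            for f, pb in zip(tb.frames, tb.position_bp):
                pa = fa.get(int(f))
                if pa is not None and abs(pa - pb) <= threshold_bp:
                    n_close += 1
                    if n_close >= min_overlap_frames:
                        hit = True
                        break
            if hit:
                break
        flags.append(hit)
    _, sd = bootstrap_fraction(flags, n_boot=n_boot, seed=seed)
    return ColocalizationResult(n_a=len(flags), n_colocalized=int(np.sum(flags)),
                                bootstrap_sd=sd, threshold_bp=threshold_bp,
                                min_overlap_frames=min_overlap_frames)


def significance_stars(p: float) -> str:
    """Figure-legend star bins: ns >0.05; * <0.05; ** <0.01; *** <0.001;
    **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   equal_var: bool = False) -> dict:
    """Two-sided two-sample t test (Welch by default) with star bins."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: zero variance in both groups
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return {"t": t, "p": p, "stars": significance_stars(p),
            "n_a": len(a), "n_b": len(b)}


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of means, rounded to one decimal (the text's "x-fold")."""
    if mean_b == 0:
        raise ValueError("zero denominator")
    return round(mean_a / mean_b, 1)


def load_fasta(path) -> str:
    """First record of a FASTA file as an uppercase sequence string."""
    from Bio import SeqIO
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def gc_profile(sequence: str, window_bp: int = 500) -> pd.DataFrame:
    """Sliding-window GC fraction along a sequence.

    Windows step by one ``window_bp`` (non-overlapping tiling); each row
    gives the window center (bp) and its GC fraction.  Non-ACGT
    characters count as non-GC, with a warning.
    """
    seq = sequence.upper()
    if len(seq) < window_bp:
        raise ValueError("sequence shorter than window")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    if not np.all(is_gc | is_at):
        warnings.warn("non-ACGT characters counted as non-GC", stacklevel=2)
    centers, fracs = [], []
    for start in range(0, len(seq) - window_bp + 1, window_bp):
        w = is_gc[start:start + window_bp]
        centers.append(start + window_bp / 2)
        fracs.append(float(w.mean()))
    return pd.DataFrame({"center_bp": centers, "gc_fraction": fracs})


def gc_at(profile: pd.DataFrame, positions_bp: Sequence[float]) -> np.ndarray:
    """GC fraction of the window containing each position."""
    centers = profile["center_bp"].to_numpy()
    fracs = profile["gc_fraction"].to_numpy()
    idx = np.clip(np.searchsorted(centers, positions_bp), 0, len(centers) - 1)
    # snap to nearest window center
    left = np.clip(idx - 1, 0, len(centers) - 1)
    use_left = np.abs(centers[left] - positions_bp) < np.abs(centers[idx] - positions_bp)
    return fracs[np.where(use_left, left, idx)]


def pause_gc_association(pause_positions_bp: Sequence[float],
                         profile: pd.DataFrame, n_random: Optional[int] = None,
                         seed: int = 0) -> dict:
    """t test of GC content at pause sites vs matched random positions.

    Random control positions are drawn uniformly over the profiled span
    (same count as pauses unless ``n_random`` is given).
    """
    pauses = np.asarray(pause_positions_bp, dtype=float)
    if pauses.size == 0:
        raise ValueError("no pause positions")
    rng = np.random.default_rng(seed)
    lo = profile["center_bp"].iloc[0]
    hi = profile["center_bp"].iloc[-1]
    n_rand = int(n_random) if n_random else pauses.size
    random_pos = rng.uniform(lo, hi, size=n_rand)
    gc_pause = gc_at(profile, pauses)
    gc_rand = gc_at(profile, random_pos)
    res = compare_groups(gc_pause, gc_rand)
    res.update({"gc_pause_mean": float(gc_pause.mean()),
                "gc_random_mean": float(gc_rand.mean())})
    return res


def summarize_cohort(condition: str, kinetics: Sequence[TrajectoryKinetics],
                     n_static: int = 0, horizon_s: float = 1800.0,
                     n_boot: int = 1000, seed: int = 0) -> CohortSummary:
    """Aggregate per-molecule kinetics into one condition summary."""
    moving = [k for k in kinetics if k.translocating]
    if not moving:
        raise ValueError("no translocating molecules")
    v = np.array([k.velocity_bp_s for k in moving])
    pr = np.array([k.processivity_kb for k in moving])
    init = initiation_fraction(moving, [None] * n_static, n_boot=n_boot, seed=seed)
    n1 = sum(1 for k in moving if k.n_pauses >= 1)
    diss = np.mean([k.bound_lifetime_s < horizon_s and k.dissociated_within_horizon
                    for k in moving])
    q1v, q3v = np.percentile(v, [25, 75])
    q1p, q3p = np.percentile(pr, [25, 75])

    def _sd(x):
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    return CohortSummary(
        condition=condition, n_molecules=len(moving),
        velocity_mean=float(v.mean()), velocity_sd=_sd(v),
        velocity_median=float(np.median(v)), velocity_iqr=(float(q1v), float(q3v)),
        processivity_mean=float(pr.mean()), processivity_sd=_sd(pr),
        processivity_median=float(np.median(pr)),
        processivity_iqr=(float(q1p), float(q3p)),
        initiation_fraction=init["fraction"], initiation_sd=init["sd"],
        frac_paused=n1 / len(moving), dissociation_fraction=float(diss))
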