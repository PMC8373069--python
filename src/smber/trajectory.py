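"""Single-particle trajectory analysis on DNA tightropes.

Position series of quantum-dot-labelled proteins moving in one dimension
along a suspended DNA substrate are reduced to mean squared displacement
(MSD) curves, diffusion coefficients ``D`` and anomalous exponents
``alpha``, motile/stationary phase calls, and two-colour colocalization
fractions.

Conventions
-----------
* positions are micrometres along the tightrope, times are seconds on a
  uniform frame grid (``dt = 1/frame_rate``);
* the MSD at lag ``n`` frames uses every overlapping start index,
  ``MSD(n*dt) = (1/(N-n)) * sum_i (x_{i+n} - x_i)**2``;
* normal 1-D diffusion follows ``MSD = 2*D*t + y`` where the intercept
  ``y`` absorbs static localization error;
* anomalous transport follows ``MSD ~ t**alpha`` and ``alpha`` is read off
  as the log-log slope;
* fits with ``R**2 < 0.8`` or using less than 10% of the MSD curve are
  flagged invalid and excluded from cohort statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "MSDProfile",
    "DiffusionEstimate",
    "PhaseSegment",
    "ColocalizationResult",
    "compute_msd",
    "fit_msd_linear",
    "fit_alpha",
    "segment_phases",
    "classify_motility",
    "motile_fraction",
    "colocalization_fraction",
]

#: validity filter defaults: estimates below either bound are discarded
R_SQUARED_MIN = 0.8
FRACTION_OF_PLOT_MIN = 0.10

#: default fraction of MSD lags entering a fit (short-lag window limits
#: the large-lag variance of time-averaged MSD estimates)
DEFAULT_FIT_FRACTION = 0.25

#: phase segmentation defaults: rolling-SD window and motile threshold
#: (3x a typical 0.03 um Qdot localization precision)
DEFAULT_SEGMENT_WINDOW = 10
DEFAULT_MOTILE_THRESHOLD = 0.09

#: colocalization defaults
DEFAULT_COLOC_THRESHOLD = 0.2
DEFAULT_MIN_OVERLAP_FRAMES = 10

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """One particle's 1-D position series along a tightrope.

    ``censored`` marks particles still bound when the observation window
    ended, so their dwell time is only bounded below.
    """

    particle_id: int
    channel: str
    times: np.ndarray
    positions: np.ndarray
    censored: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or positions.ndim != 1 or times.size != positions.size:
            raise ValueError("times and positions must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError(
                f"trajectory {self.particle_id}: need at least 2 frames, got {times.size}"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise ValueError(f"trajectory {self.particle_id}: non-finite values")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError(f"trajectory {self.particle_id}: times not strictly increasing")
        if np.any(np.abs(dt - dt[0]) > _GRID_TOL):
            raise ValueError(f"trajectory {self.particle_id}: frame grid not uniform")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class MSDProfile:
    """Time-averaged MSD curve of one trajectory (or phase)."""

    lags: np.ndarray            # lag in frames, n = 1 .. n_max
    lag_times: np.ndarray       # n * dt, seconds
    msd: np.ndarray             # um^2
    n_pairs: np.ndarray         # displacement pairs per lag, N - n
    n_frames: int               # N of the source series (full plot has N-1 lags)

    def __post_init__(self) -> None:
        if np.any(self.msd < 0):
            raise ValueError("MSD cannot be negative")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be ascending")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion parameters from an MSD fit.

    ``valid`` applies the quality filter (R^2 >= 0.8 and the fit spanning
    at least 10% of the MSD plot); invalid estimates are retained for
    inspection but excluded from cohort summaries.
    """

    D: float                    # um^2/s
    y_intercept: float          # um^2
    alpha: float
    r_squared: float
    fraction_of_plot_used: float
    valid: bool
    n_points_used: int = 0

    @staticmethod
    def invalid() -> "DiffusionEstimate":
        return DiffusionEstimate(
            D=math.nan, y_intercept=math.nan, alpha=math.nan,
            r_squared=math.nan, fraction_of_plot_used=0.0, valid=False,
        )


@dataclass(frozen=True)
class PhaseSegment:
    particle_id: int
    start_frame: int
    end_frame: int              # inclusive
    label: str                  # "motile" | "stationary"

    def __post_init__(self) -> None:
        if self.label not in ("motile", "stationary"):
            raise ValueError(f"unknown phase label {self.label!r}")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame before start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ColocalizationResult:
    """Two-colour colocalization counts, Venn convention.

    The fraction is taken over the union of particles so a colocalized
    pair counts once: ``n_coloc / (n_a + n_b - n_coloc)``.
    """

    n_channel_a: int
    n_channel_b: int
    n_colocalized: int
    fraction_colocalized: float
    pairs: tuple = ()
    empty_channel_warning: bool = False


# ---------------------------------------------------------------------------
# MSD and diffusion fits
# ---------------------------------------------------------------------------

def compute_msd(traj: Trajectory, max_lag_fraction: float = 1.0) -> MSDProfile:
    """Time-averaged MSD over all overlapping start indices.

    ``MSD(n*dt) = (1/(N-n)) * sum_{i=1}^{N-n} (x_{i+n} - x_i)**2`` for
    lags ``n = 1 .. floor(max_lag_fraction * (N-1))``.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    x = traj.positions
    n_frames = traj.n_frames
    n_max = max(1, int(math.floor(max_lag_fraction * (n_frames - 1))))
    lags = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    n_pairs = n_frames - lags
    for j, n in enumerate(lags):
        d = x[n:] - x[:-n]
        msd[j] = np.sum(d * d) / (n_frames - n)
    return MSDProfile(
        lags=lags,
        lag_times=lags * traj.dt,
        msd=msd,
        n_pairs=n_pairs,
        n_frames=n_frames,
    )


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def _apply_filter(r2: float, frac: float,
                  r2_min: float = R_SQUARED_MIN,
                  frac_min: float = FRACTION_OF_PLOT_MIN) -> bool:
    return bool(r2 >= r2_min and frac >= frac_min)


def fit_msd_linear(profile: MSDProfile,
                   fit_fraction: float = DEFAULT_FIT_FRACTION) -> DiffusionEstimate:
    """Fit ``MSD = 2*D*t + y`` by OLS over the first ``fit_fraction`` of lags.

    The slope gives ``D``, the intercept ``y`` absorbs localization error.
    Returns an invalid estimate (never raises) when fewer than 3 lag
    points fall in the fit range.
    """
    if not 0 < fit_fraction <= 1:
        raise ValueError("fit_fraction must be in (0, 1]")
    n_use = max(1, int(math.ceil(fit_fraction * profile.lags.size)))
    t = profile.lag_times[:n_use]
    y = profile.msd[:n_use]
    if t.size < 3:
        return DiffusionEstimate.invalid()
    slope, intercept = np.polyfit(t, y, 1)
    r2 = _r_squared(y, slope * t + intercept)
    frac = t.size / (profile.n_frames - 1)
    return DiffusionEstimate(
        D=float(slope / 2.0),
        y_intercept=float(intercept),
        alpha=math.nan,
        r_squared=r2,
        fraction_of_plot_used=frac,
        valid=_apply_filter(r2, frac),
        n_points_used=int(t.size),
    )


def fit_alpha(profile: MSDProfile,
              fit_fraction: float = DEFAULT_FIT_FRACTION) -> DiffusionEstimate:
    """Anomalous exponent from the log-log slope of the MSD curve.

    ``log MSD = log(2*D) + alpha * log t`` over the first ``fit_fraction``
    of lags; non-positive MSD values are dropped before taking logs. The
    recovered ``D`` is ``exp(intercept)/2`` so that the Brownian case
    (alpha = 1) reproduces the linear-fit ``D`` exactly on noiseless
    input.
    """
    if not 0 < fit_fraction <= 1:
        raise ValueError("fit_fraction must be in (0, 1]")
    n_use = max(1, int(math.ceil(fit_fraction * profile.lags.size)))
    t = profile.lag_times[:n_use]
    y = profile.msd[:n_use]
    keep = y > 0
    t, y = t[keep], y[keep]
    if t.size < 3:
        return DiffusionEstimate.invalid()
    log_t, log_y = np.log(t), np.log(y)
    slope, intercept = np.polyfit(log_t, log_y, 1)
    r2 = _r_squared(log_y, slope * log_t + intercept)
    frac = t.size / (profile.n_frames - 1)
    return DiffusionEstimate(
        D=float(math.exp(intercept) / 2.0),
        y_intercept=0.0,
        alpha=float(slope),
        r_squared=r2,
        fraction_of_plot_used=frac,
        valid=_apply_filter(r2, frac),
        n_points_used=int(t.size),
    )


# ---------------------------------------------------------------------------
# Phase segmentation and motility
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[list]:
    """Contiguous [start, end, label] runs of a boolean/label array."""
    runs: list[list] = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append([start, i - 1, labels[start]])
            start = i
    return runs


def segment_phases(traj: Trajectory,
                   window_frames: int = DEFAULT_SEGMENT_WINDOW,
                   motile_threshold: float = DEFAULT_MOTILE_THRESHOLD,
                   min_phase_frames: int | None = None) -> list[PhaseSegment]:
    """Split a trajectory into motile and stationary phases.

    A frame is provisionally motile when the rolling standard deviation of
    position over ``window_frames`` exceeds ``motile_threshold``; runs
    shorter than ``min_phase_frames`` (default: the window) are absorbed
    into their longer neighbour. A trajectory shorter than the window gets
    a single segment labelled by its whole-series SD.
    """
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    if min_phase_frames is None:
        min_phase_frames = window_frames
    x = traj.positions
    n = x.size
    whole_label = "motile" if float(np.std(x, ddof=1)) > motile_threshold else "stationary"
    if n < window_frames:
        return [PhaseSegment(traj.particle_id, 0, n - 1, whole_label)]

    roll = (
        pd.Series(x)
        .rolling(window_frames, center=True, min_periods=max(3, window_frames // 2))
        .std()
        .to_numpy()
    )
    motile = np.where(np.isnan(roll), False, roll > motile_threshold)

    runs = _runs(motile)
    # absorb short runs into the longer neighbour until all runs are long
    # enough (or only one run remains)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[1] - r[0] + 1 for r in runs]
        order = np.argsort(lengths)
        for idx in order:
            if lengths[idx] >= min_phase_frames:
                continue
            if idx == 0:
                runs[1][0] = runs[0][0]
                del runs[0]
            elif idx == len(runs) - 1:
                runs[-2][1] = runs[-1][1]
                del runs[-1]
            else:
                left_len = runs[idx - 1][1] - runs[idx - 1][0] + 1
                right_len = runs[idx + 1][1] - runs[idx + 1][0] + 1
                if left_len >= right_len:
                    runs[idx - 1][1] = runs[idx][1]
                else:
                    runs[idx + 1][0] = runs[idx][0]
                del runs[idx]
            changed = True
            break
        # merge adjacent runs that now share a label
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    return [
        PhaseSegment(traj.particle_id, int(s), int(e),
                     "motile" if lab else "stationary")
        for s, e, lab in runs
    ]


def classify_motility(segments: list[PhaseSegment]) -> str:
    """A particle is motile iff it shows at least one motile phase."""
    if not segments:
        raise ValueError("empty segment list")
    return "motile" if any(s.label == "motile" for s in segments) else "stationary"


def motile_fraction(calls: list[str]) -> float:
    """Fraction of a cohort classified motile."""
    if not calls:
        raise ValueError("empty cohort")
    return sum(c == "motile" for c in calls) / len(calls)


# ---------------------------------------------------------------------------
# Two-colour colocalization
# ---------------------------------------------------------------------------

def _frame_index(traj: Trajectory) -> np.ndarray:
    return np.round(traj.times / traj.dt).astype(np.int64)


def colocalization_fraction(
    trajs_a: list[Trajectory],
    trajs_b: list[Trajectory],
    distance_threshold: float = DEFAULT_COLOC_THRESHOLD,
    min_overlap_frames: int = DEFAULT_MIN_OVERLAP_FRAMES,
) -> ColocalizationResult:
    """Greedy one-to-one two-colour colocalization.

    A cross-channel pair is a candidate when its positions sit within
    ``distance_threshold`` for at least ``min_overlap_frames`` concurrent
    frames. Candidates are matched greedily by ascending mean pair
    distance (ties broken by lower particle ids) and the colocalized
    fraction is reported over the union of particles, so one pair counts
    as a single entity (Venn convention).
    """
    channels_a = {t.channel for t in trajs_a}
    channels_b = {t.channel for t in trajs_b}
    if channels_a & channels_b:
        raise ValueError(f"channels must be distinct, both contain {channels_a & channels_b}")
    n_a, n_b = len(trajs_a), len(trajs_b)
    if n_a == 0 or n_b == 0:
        return ColocalizationResult(n_a, n_b, 0, 0.0, (), empty_channel_warning=True)

    idx_a_all = [_frame_index(t) for t in trajs_a]
    idx_b_all = [_frame_index(t) for t in trajs_b]
    span_a = [(t.positions.min(), t.positions.max()) for t in trajs_a]
    span_b = [(t.positions.min(), t.positions.max()) for t in trajs_b]

    candidates = []
    for a, ia, (lo_a, hi_a) in zip(trajs_a, idx_a_all, span_a):
        for b, ib, (lo_b, hi_b) in zip(trajs_b, idx_b_all, span_b):
            # position ranges further apart than the threshold can never
            # produce a close frame
            if max(lo_a, lo_b) - min(hi_a, hi_b) > distance_threshold:
                continue
            common, idx_a, idx_b = np.intersect1d(ia, ib, return_indices=True)
            if common.size < min_overlap_frames:
                continue
            dist = np.abs(a.positions[idx_a] - b.positions[idx_b])
            close = dist <= distance_threshold
            if int(np.sum(close)) >= min_overlap_frames:
                candidates.append(
                    (float(np.mean(dist[close])), a.particle_id, b.particle_id)
                )
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for _, pa, pb in candidates:
        if pa in used_a or pb in used_b:
            continue
        used_a.add(pa)
        used_b.add(pb)
        pairs.append((pa, pb))
    n_coloc = len(pairs)
    fraction = n_coloc / (n_a + n_b - n_coloc)
    return ColocalizationResult(n_a, n_b, n_coloc, fraction, tuple(pairs))
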