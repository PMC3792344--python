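"""Quantification of 1D nucleoid-intensity profiles and focus tracks.

Two measurement procedures used on live-cell data, implemented on
already-extracted 1D inputs:

- nucleoid separation from an axial DNA-stain intensity profile: when the
  profile shows two lobes with an interior valley, report the *depth* of
  separation ``R = 1 - I_valley / mean(I_peak1, I_peak2)`` (0 = merged,
  1 = fully resolved) and the *distance* ``D`` between the intensity-weighted
  centers of mass of the two lobes split at the valley;
- apparent diffusion of fluorescent replication-fork foci from 2D tracks:
  time- and ensemble-averaged mean squared displacement (MSD) per lag, and
  the short-time apparent diffusion coefficient ``D_app = slope / 4``.

A 2D Brownian track generator (optionally confined to a disc) provides
synthetic inputs with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "IntensityProfile1D",
    "SeparationResult",
    "FocusTrack",
    "nucleoid_separation",
    "simulate_focus_tracks",
    "msd_curve",
    "apparent_diffusion",
    "DiffusionEstimate",
]


@dataclass
class IntensityProfile1D:
    """Background-subtracted intensity vs axial position (any length unit)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be matching 1D arrays")
        if len(self.positions) < 8:
            raise ValueError("need at least 8 profile samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class SeparationResult:
    R: float            # separation depth in [0, 1]
    D: float            # lobe CM distance, in the profile's position units
    n_nucleoids: int    # 1 or 2

    def __post_init__(self):
        if self.n_nucleoids == 1 and (self.R != 0 or self.D != 0):
            raise ValueError("single nucleoid implies R = D = 0")
        if not (0 <= self.R <= 1) or self.D < 0:
            raise ValueError("require 0 <= R <= 1 and D >= 0")


@dataclass
class FocusTrack:
    """One tracked focus: uniformly sampled 2D positions (microns, seconds)."""

    frame_times: np.ndarray
    xy_positions: np.ndarray

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.xy_positions = np.asarray(self.xy_positions, dtype=float)
        if len(self.frame_times) < 2:
            raise ValueError("a track needs at least 2 frames")
        dt = np.diff(self.frame_times)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("frame times must be uniformly increasing")
        if self.xy_positions.shape != (len(self.frame_times), 2):
            raise ValueError("xy_positions must be (n_frames, 2)")

    @property
    def dt(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the moving average keeps length and does not sag at edges
    pad = window // 2
    yp = np.r_[y[pad:0:-1], y, y[-2 : -2 - pad : -1]]
    out = np.convolve(yp, kernel, mode="same")[pad : pad + len(y)]
    return out


def nucleoid_separation(
    profile: IntensityProfile1D,
    smoothing_window: int = 3,
    min_prominence: float = 0.05,
) -> SeparationResult:
    """Depth R and distance D of nucleoid separation from an axial profile.

    The profile is moving-average smoothed, peaks are detected by prominence
    (threshold ``min_prominence`` as a fraction of the smoothed maximum).
    With two dominant peaks and an interior minimum the profile is split at
    the valley; D is the distance between the intensity-weighted lobe centers
    and R = 1 - I_valley / mean(I_peaks).  Otherwise a single nucleoid is
    reported with R = D = 0.
    """
    x = profile.positions
    y = _smooth(profile.intensities, smoothing_window)
    if y.max() <= 0:
        return SeparationResult(0.0, 0.0, 1)
    peaks, props = find_peaks(y, prominence=min_prominence * y.max())
    if len(peaks) < 2:
        return SeparationResult(0.0, 0.0, 1)
    # two most prominent peaks, in positional order
    order = np.argsort(props["prominences"])[::-1][:2]
    p1, p2 = sorted(peaks[order])
    valley = p1 + int(np.argmin(y[p1 : p2 + 1]))
    i_valley = y[valley]
    i_peaks = 0.5 * (y[p1] + y[p2])
    r = float(np.clip(1.0 - i_valley / i_peaks, 0.0, 1.0))
    left_x, left_y = x[: valley + 1], y[: valley + 1]
    right_x, right_y = x[valley:], y[valley:]
    if left_y.sum() <= 0 or right_y.sum() <= 0:
        return SeparationResult(0.0, 0.0, 1)
    cm_left = float((left_x * left_y).sum() / left_y.sum())
    cm_right = float((right_x * right_y).sum() / right_y.sum())
    return SeparationResult(r, abs(cm_right - cm_left), 2)


def simulate_focus_tracks(
    n_tracks: int,
    n_frames: int,
    dt: float = 0.05,
    D0: float = 0.05,
    confinement_radius: float | None = None,
    seed=0,
) -> list:
    """Synthetic 2D Brownian focus tracks with diffusion coefficient ``D0``.

    Steps are Gaussian with per-coordinate variance ``2*D0*dt``; when
    ``confinement_radius`` is given, positions are reflected back into a
    disc of that radius about the origin.  Deterministic given ``seed``.
    """
    if n_tracks <= 0 or n_frames < 2 or dt <= 0 or D0 < 0:
        raise ValueError("need n_tracks > 0, n_frames >= 2, dt > 0, D0 >= 0")
    if confinement_radius is not None and confinement_radius <= 0:
        raise ValueError("confinement_radius must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt
    sigma = np.sqrt(2.0 * D0 * dt)
    steps = rng.normal(0.0, sigma, size=(n_tracks, n_frames - 1, 2)) if sigma > 0 else np.zeros(
        (n_tracks, n_frames - 1, 2)
    )
    if confinement_radius is None:
        xy = np.concatenate(
            [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
    else:
        xy = np.zeros((n_tracks, n_frames, 2))
        for t in range(1, n_frames):
            nxt = xy[:, t - 1] + steps[:, t - 1]
            r = np.sqrt((nxt**2).sum(axis=1))
            out = r > confinement_radius
            if out.any():
                # radial reflection about the boundary
                scale = (2 * confinement_radius - r[out]) / r[out]
                nxt[out] *= np.clip(scale, 0.0, None)[:, None]
            xy[:, t] = nxt
    return [FocusTrack(times, xy[k]) for k in range(n_tracks)]


def msd_curve(tracks, max_lag: int):
    """Time- and ensemble-averaged MSD per lag, pooled over all frame pairs.

    Returns ``(lag_times, msd, sem)`` where ``sem`` is the standard error of
    the pooled squared displacements at each lag (pairs overlap in time, so
    sem understates the true uncertainty at large lags; the short-time fit
    used for D_app is insensitive to this).
    """
    if not tracks:
        raise ValueError("no tracks given")
    shortest = min(len(t.frame_times) for t in tracks)
    if not (1 <= max_lag < shortest):
        raise ValueError(f"max_lag must be in [1, {shortest - 1}]")
    dt = tracks[0].dt
    lag_times = np.arange(1, max_lag + 1) * dt
    msd = np.empty(max_lag)
    sem = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        sq = np.concatenate(
            [
                ((t.xy_positions[lag:] - t.xy_positions[:-lag]) ** 2).sum(axis=1)
                for t in tracks
            ]
        )
        msd[lag - 1] = sq.mean()
        sem[lag - 1] = sq.std(ddof=1) / np.sqrt(len(sq)) if len(sq) > 1 else 0.0
    return lag_times, msd, sem


class DiffusionEstimate(NamedTuple):
    D: float            # apparent diffusion coefficient, position units^2 / s
    degenerate: bool    # True when the MSD carried no signal


def apparent_diffusion(lag_times, msd, fit_lags: int = 4) -> DiffusionEstimate:
    """Short-time apparent diffusion coefficient: MSD slope over the first
    ``fit_lags`` lags divided by 4 (2D convention)."""
    lag_times = np.asarray(lag_times, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if fit_lags < 2 or len(lag_times) < fit_lags:
        raise ValueError("need at least 2 fit lags")
    t, m = lag_times[:fit_lags], msd[:fit_lags]
    if np.allclose(m, 0.0):
        return DiffusionEstimate(0.0, True)
    slope = np.polyfit(t, m, 1)[0]
    return DiffusionEstimate(float(slope / 4.0), False)
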