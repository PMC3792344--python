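"""Time-resolved axial MinD gradient profiles.

MinD oscillates pole-to-pole in *E. coli* with a period of tens of seconds,
producing an axial concentration profile that is maximal at the currently
occupied pole and decays toward mid-cell.  This module provides such profile
series — loaded from measured-style TSV tables or generated synthetically —
and converts them into the time-varying binding-probability field that
drives the ``mind_profile`` tether mode.

Conversion conventions: intensities are max-normalized *per frame* (so the
occupied pole saturates the field every half-cycle regardless of total
fluorescence), interpolated linearly in the axial coordinate, and looked up
nearest-frame in time with cyclic wrap.  ``mcs_per_second`` maps wall-clock
seconds of the measurement onto simulation MCS; the default makes one full
oscillation span 10^4 MCS, matching the idealized oscillating gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MinDProfileSeries",
    "load_profile_series",
    "save_profile_series",
    "synthesize_oscillation",
    "profile_to_field",
    "profile_field_value",
    "build_profile_table",
]

#: default frame spacing of the fluorescence time-lapse, seconds
DEFAULT_FRAME_SPACING_S = 7.0
#: default full oscillation period of the synthetic Min cycle, seconds
DEFAULT_PERIOD_S = 56.0
#: default time mapping: one 56 s oscillation = 10^4 MCS
DEFAULT_MCS_PER_SECOND = 10_000 / DEFAULT_PERIOD_S


@dataclass
class MinDProfileSeries:
    """Axial MinD intensity profiles over time.

    frame_times : seconds, strictly increasing; axial_bins : relative cell
    length in [0, 1], increasing; intensities : (frames, bins), arbitrary
    fluorescence units >= 0, every frame having at least one positive bin;
    mcs_per_second : factor mapping measurement seconds to simulation MCS.
    """

    frame_times: np.ndarray
    axial_bins: np.ndarray
    intensities: np.ndarray
    mcs_per_second: float = DEFAULT_MCS_PER_SECOND

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.axial_bins = np.asarray(self.axial_bins, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.frame_times), len(self.axial_bins)):
            raise ValueError("intensities must be (n_frames, n_bins)")
        if len(self.frame_times) < 1 or len(self.axial_bins) < 2:
            raise ValueError("need at least 1 frame and 2 axial bins")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(np.diff(self.axial_bins) <= 0):
            raise ValueError("axial_bins must be strictly increasing")
        if self.axial_bins[0] < 0 or self.axial_bins[-1] > 1:
            raise ValueError("axial_bins must lie within [0, 1]")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if np.any(self.intensities.max(axis=1) <= 0):
            raise ValueError("every frame needs at least one positive bin")
        if self.mcs_per_second <= 0:
            raise ValueError("mcs_per_second must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def frame_spacing_s(self) -> float:
        if self.n_frames < 2:
            return DEFAULT_FRAME_SPACING_S
        return float(np.median(np.diff(self.frame_times)))

    @property
    def duration_s(self) -> float:
        """Cyclic duration: span of frame times plus one frame spacing."""
        return float(self.frame_times[-1] - self.frame_times[0] + self.frame_spacing_s)

    def normalized(self) -> np.ndarray:
        """Per-frame max-normalized intensities (each frame peaks at 1)."""
        return self.intensities / self.intensities.max(axis=1, keepdims=True)


def load_profile_series(path, mcs_per_second: float = DEFAULT_MCS_PER_SECOND) -> MinDProfileSeries:
    """Read a profile series from TSV: header ``time <bin> <bin> ...``, one
    row per frame.  Raises a parse error naming the offending line."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty profile file") from None
    if df.shape[1] < 3 or df.columns[0] != "time":
        raise ValueError(f"{path}: header must be 'time' followed by >=2 axial bin coordinates")
    try:
        bins = np.array([float(c) for c in df.columns[1:]])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric bin coordinate in header: {e}") from None
    vals = df.to_numpy(dtype=float)
    times, intens = vals[:, 0], vals[:, 1:]
    neg = np.argwhere(intens < 0)
    if len(neg):
        r = int(neg[0, 0])
        raise ValueError(f"{path}: negative intensity on data line {r + 2}")
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        raise ValueError(f"{path}: non-monotonic frame time on data line {int(bad[0]) + 3}")
    return MinDProfileSeries(times, bins, intens, mcs_per_second=mcs_per_second)


def save_profile_series(series: MinDProfileSeries, path) -> None:
    """Write the TSV format read by :func:`load_profile_series` (round-trips)."""
    cols = ["time"] + [repr(float(b)) for b in series.axial_bins]
    df = pd.DataFrame(
        np.column_stack([series.frame_times, series.intensities]), columns=cols
    )
    df.to_csv(path, sep="\t", index=False)


def synthesize_oscillation(
    period_s: float = DEFAULT_PERIOD_S,
    n_frames: int = 40,
    n_bins: int = 32,
    sharpness: float = 1.0,
    frame_spacing_s: float = DEFAULT_FRAME_SPACING_S,
    noise: float = 0.0,
    seed=0,
    mcs_per_second: float | None = None,
) -> MinDProfileSeries:
    """Generate a pole-to-pole alternating polar-cap profile series.

    Within each half-period the intensity is maximal at the occupied pole and
    decays toward mid-cell as ``(1 - 2u)**sharpness`` in the distance-from-
    pole coordinate ``u`` (zero beyond mid-cell); the occupied pole switches
    every half-period.  ``noise`` adds multiplicative lognormal-ish jitter
    (1 + noise*eps, clipped at 0), seeded deterministically.  Frames are
    spaced ``frame_spacing_s`` apart (7 s mimics the time-lapse cadence).
    """
    if period_s <= 0:
        raise ValueError("period_s must be > 0")
    if n_bins < 8:
        raise ValueError("need n_bins >= 8")
    bins = (np.arange(n_bins) + 0.5) / n_bins
    times = np.arange(n_frames) * frame_spacing_s
    half = period_s / 2.0
    intens = np.empty((n_frames, n_bins))
    floor = 1e-3  # faint cytoplasmic background keeps frames strictly positive
    for f, t in enumerate(times):
        left_active = (int(t // half) % 2) == 0
        u = bins if left_active else 1.0 - bins
        cap = np.clip(1.0 - 2.0 * u, 0.0, None) ** sharpness
        intens[f] = cap + floor
    if noise > 0:
        rng = np.random.default_rng(seed)
        intens = np.clip(intens * (1.0 + noise * rng.standard_normal(intens.shape)), 0.0, None)
        intens += floor
    mps = DEFAULT_MCS_PER_SECOND if mcs_per_second is None else mcs_per_second
    if mcs_per_second is None and period_s != DEFAULT_PERIOD_S:
        mps = 10_000 / period_s  # keep one oscillation = 10^4 MCS
    return MinDProfileSeries(times, bins, intens, mcs_per_second=mps)


def _nearest_frame(series: MinDProfileSeries, t_s: float) -> int:
    """Nearest frame index to time ``t_s`` with cyclic wrap."""
    t0 = series.frame_times[0]
    tt = t0 + (t_s - t0) % series.duration_s
    dist = np.abs(series.frame_times - tt)
    dist = np.minimum(dist, series.duration_s - dist)
    return int(np.argmin(dist))


def profile_field_value(series: MinDProfileSeries, x_rel, mcs_clock: int):
    """Normalized field intensity in [0, 1] at relative position and MCS time."""
    t_s = mcs_clock / series.mcs_per_second
    f = _nearest_frame(series, t_s)
    return np.interp(x_rel, series.axial_bins, series.normalized()[f])


def profile_to_field(series: MinDProfileSeries, p_max: float):
    """Return ``field(x_rel, mcs)`` giving the binding probability in
    ``[0, p_max]`` (per-frame max normalization, linear in x, nearest frame
    in time with cyclic wrap)."""

    def field(x_rel, mcs_clock):
        return p_max * profile_field_value(series, x_rel, mcs_clock)

    return field


def build_profile_table(series: MinDProfileSeries, p_max: float, centers_rel: np.ndarray):
    """Tabulate the profile field for the simulation kernel.

    Returns ``(table, slot_of_mcs)`` where ``table[f, px]`` is the binding
    probability of frame ``f`` at lattice position ``px`` and
    ``slot_of_mcs`` maps ``clock % duration_mcs`` to the nearest frame.
    """
    norm = series.normalized()
    table = np.stack([p_max * np.interp(centers_rel, series.axial_bins, row) for row in norm])
    duration_mcs = max(1, int(round(series.duration_s * series.mcs_per_second)))
    t_s = np.arange(duration_mcs) / series.mcs_per_second
    t0 = series.frame_times[0]
    tt = t0 + (t_s - t0) % series.duration_s
    dist = np.abs(series.frame_times[None, :] - tt[:, None])
    dist = np.minimum(dist, series.duration_s - dist)
    slot = np.argmin(dist, axis=1).astype(np.int64)
    return table, slot
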