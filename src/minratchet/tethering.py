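"""Membrane tethering fields and bind/release dynamics (the Brownian ratchet).

A tethering site transiently immobilizes a chromosome segment (monomer) that
is close to the lateral membrane.  The spatial distribution of sites is one
of five regimes:

``none``
    no tethering (pure entropic model);
``uniform``
    constant binding probability everywhere along the cell;
``static_gradient``
    ``p(x) = p_max * (2|x/Lx - 1/2|)**s`` — zero at mid-cell, maximal at the
    poles, steepness exponent ``s``;
``oscillating_gradient``
    the static profile restricted to one axial half, the active half
    switching every ``period`` MCS (an idealized Min oscillation);
``mind_profile``
    binding probability proportional to a measured (or synthetic) MinD axial
    fluorescence profile series, max-normalized per frame.

Binding is only possible for monomers within ``border_distance`` lattice
units of a *lateral* wall (y or z); the pole caps carry no tether sites.
A bound monomer is frozen in place for a geometrically distributed dwell
time with mean ``dwell_mean`` MCS, then released.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MODES",
    "TetherFieldSpec",
    "is_at_border",
    "binding_probability",
    "build_field_table",
    "update_tethers",
]

MODES = ("none", "uniform", "static_gradient", "oscillating_gradient", "mind_profile")

#: default mean dwell time of a tether, in MCS
DEFAULT_DWELL_MEAN = 100.0
#: default half-cycle of the idealized oscillating gradient, in MCS
DEFAULT_PERIOD = 5_000


@dataclass
class TetherFieldSpec:
    """Parameters of the tethering-site field.

    p_max : binding probability per MCS for an eligible monomer at the field
        maximum; steepness : gradient exponent ``s >= 0``; dwell_mean : mean
        immobilization time (MCS); period : half-cycle of the oscillating
        gradient (MCS); border_distance : lateral-wall proximity that makes a
        monomer tether-eligible (lattice units); profile : MinDProfileSeries,
        required iff mode == 'mind_profile'.
    """

    mode: str = "none"
    p_max: float = 0.1
    steepness: float = 1.0
    dwell_mean: float = DEFAULT_DWELL_MEAN
    period: int = DEFAULT_PERIOD
    border_distance: int = 1
    profile: Optional[object] = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown tether mode {self.mode!r}; choose from {MODES}")
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError("p_max must lie in [0, 1]")
        if self.steepness < 0:
            raise ValueError("steepness must be >= 0")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be > 0")
        if self.mode == "oscillating_gradient" and self.period <= 0:
            raise ValueError("period must be > 0 for oscillating modes")
        if (self.profile is not None) != (self.mode == "mind_profile"):
            raise ValueError("profile must be given exactly when mode == 'mind_profile'")


def is_at_border(position, box, d_b: int = 1) -> bool:
    """True iff the monomer cube lies within ``d_b`` of a lateral (y/z) wall.

    The x-extreme pole caps are not tether-eligible: only the cylindrical
    membrane carries sites.  The gap between cube face and wall must be
    strictly less than ``d_b`` (touching wall = gap 0).
    """
    _, y, z = (int(c) for c in position)
    gap_y = min(y, box.Ly - 1 - y)
    gap_z = min(z, box.Lz - 1 - z)
    return min(gap_y, gap_z) < d_b


def _static_profile(x_rel: np.ndarray, p_max: float, s: float) -> np.ndarray:
    return p_max * (2.0 * np.abs(x_rel - 0.5)) ** s


def binding_probability(x_axial: float, mcs_clock: int, spec: TetherFieldSpec, box) -> float:
    """Per-MCS binding probability at axial position ``x_axial`` and time.

    Analytic field; ``x_axial`` is a physical coordinate in ``[0, Lx]``.
    The kernel uses a tabulated version of this function (see
    :func:`build_field_table`).
    """
    x = np.asarray(x_axial, dtype=float)
    if np.any(x < 0) or np.any(x > box.Lx):
        raise ValueError(f"x_axial outside [0, {box.Lx}]")
    rel = x / box.Lx
    if spec.mode == "none":
        p = np.zeros_like(rel)
    elif spec.mode == "uniform":
        p = np.full_like(rel, spec.p_max)
    elif spec.mode == "static_gradient":
        p = _static_profile(rel, spec.p_max, spec.steepness)
    elif spec.mode == "oscillating_gradient":
        half = (int(mcs_clock) % (2 * spec.period)) // spec.period  # 0: left pole active
        p = _static_profile(rel, spec.p_max, spec.steepness)
        active = rel < 0.5 if half == 0 else rel >= 0.5
        p = np.where(active, p, 0.0)
    else:  # mind_profile
        from .min_profile import profile_field_value

        p = spec.p_max * profile_field_value(spec.profile, rel, mcs_clock)
    return float(p) if np.isscalar(x_axial) else p


def build_field_table(spec: TetherFieldSpec, box):
    """Tabulate the field for the kernel.

    Returns ``(table, slot_of_mcs)``: ``table[slot, px]`` is the binding
    probability for a monomer whose cube lower corner sits at axial position
    ``px`` (cube center ``px + 0.5``); ``slot_of_mcs[clock % len]`` selects
    the active time slot.
    """
    Lx = box.Lx
    centers_rel = (np.arange(Lx) + 0.5) / Lx
    if spec.mode == "none":
        return np.zeros((1, Lx)), np.zeros(1, dtype=np.int64)
    if spec.mode == "uniform":
        return np.full((1, Lx), spec.p_max), np.zeros(1, dtype=np.int64)
    if spec.mode == "static_gradient":
        return _static_profile(centers_rel, spec.p_max, spec.steepness)[None, :], np.zeros(
            1, dtype=np.int64
        )
    if spec.mode == "oscillating_gradient":
        base = _static_profile(centers_rel, spec.p_max, spec.steepness)
        left = np.where(centers_rel < 0.5, base, 0.0)
        right = np.where(centers_rel >= 0.5, base, 0.0)
        table = np.stack([left, right])
        slot_of_mcs = np.zeros(2 * spec.period, dtype=np.int64)
        slot_of_mcs[spec.period :] = 1
        return table, slot_of_mcs
    # mind_profile
    from .min_profile import build_profile_table

    return build_profile_table(spec.profile, spec.p_max, centers_rel)


def update_tethers(state, spec: TetherFieldSpec) -> None:
    """One tether-field update (pure-Python reference; kernel mirrors this).

    Releases every bound monomer whose dwell has expired, then lets every
    unbound border-eligible monomer bind with the field probability at its
    axial center.  Dwell durations are geometric (support >= 1) with mean
    ``spec.dwell_mean``.  No randomness is consumed where the local binding
    probability is zero.
    """
    clock = state.mcs_clock
    for i in range(state.M):
        if state.tethered[i] and state.release_mcs[i] <= clock:
            state.tethered[i] = False
        if not state.tethered[i]:
            if not is_at_border(state.pos[i], state.box, spec.border_distance):
                continue
            p = binding_probability(state.pos[i, 0] + 0.5, clock, spec, state.box)
            if p > 0.0 and state.rng.random() < p:
                state.tethered[i] = True
                u = state.rng.random()
                q = 1.0 / spec.dwell_mean
                k = 1 if q >= 1.0 else max(1, int(np.ceil(np.log1p(-u) / np.log1p(-q))))
                state.release_mcs[i] = clock + k
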