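"""Per-run and ensemble observables of the segregation simulations.

The primary readout is the relative axial center of mass (CM) of each ring,
``cm_rel = (<x_center> - Lx/2) / Lx`` in [-1/2, 1/2] (0 = mid-cell), tracked
over Monte-Carlo time; axial density profiles, the radius of gyration, the
cross-run CM distribution, and the force-distance probe (equilibrium CM
separation under an applied attractive inter-ring force) complete the
measurement side of the simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "center_of_mass_rel",
    "density_profile",
    "radius_of_gyration",
    "ObservableSeries",
    "EnsembleSummary",
    "summarize_ensemble",
    "ForceDistancePoint",
    "force_distance_curve",
]


def _positions(polymer) -> np.ndarray:
    return polymer.positions if hasattr(polymer, "positions") else np.asarray(polymer)


def center_of_mass_rel(polymer, box) -> float:
    """Relative axial CM: mean monomer-center x minus Lx/2, over Lx."""
    pos = _positions(polymer)
    return float((pos[:, 0].mean() + 0.5 - box.Lx / 2) / box.Lx)


def density_profile(polymer, box, n_bins: int | None = None) -> np.ndarray:
    """Normalized axial monomer histogram (fraction per bin, sums to 1)."""
    pos = _positions(polymer)
    n_bins = box.Lx if n_bins is None else int(n_bins)
    if n_bins <= 0 or box.Lx % n_bins:
        raise ValueError(f"n_bins must divide Lx={box.Lx}")
    centers = pos[:, 0] + 0.5
    hist, _ = np.histogram(centers, bins=n_bins, range=(0, box.Lx))
    return hist / len(pos)


def radius_of_gyration(polymer) -> float:
    """RMS distance of monomer centers from their 3D centroid, lattice units."""
    c = _positions(polymer) + 0.5
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum(axis=1).mean()))


@dataclass
class ObservableSeries:
    """Time series of one run: CM trajectories and density snapshots."""

    mcs_points: np.ndarray                  # (T,)
    cm_rel: np.ndarray                      # (T, n_polymers)
    labels: list
    density_snapshots: dict = field(default_factory=dict)  # mcs -> (n_poly, n_bins)

    def __post_init__(self):
        if np.any(np.abs(self.cm_rel) > 0.5):
            raise ValueError("cm_rel outside [-0.5, 0.5]")
        for mcs, snap in self.density_snapshots.items():
            if not np.allclose(np.asarray(snap).sum(axis=-1), 1.0):
                raise ValueError(f"density snapshot at {mcs} MCS is not normalized")

    def final_abs_cm(self, tail: int = 1) -> np.ndarray:
        """Per-polymer |cm_rel| averaged over the trailing ``tail`` records
        (the steady-state estimator; ``tail=1`` is the raw last point)."""
        return np.abs(self.cm_rel[-tail:]).mean(axis=0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mcs": self.mcs_points}
            | {f"cm_rel_{lab}": self.cm_rel[:, i] for i, lab in enumerate(self.labels)}
        )


@dataclass
class EnsembleSummary:
    """Cross-run summary of one experimental condition.

    ``final_cm`` holds the signed final cm_rel of the polymer labelled
    'right' in each run (the cross-run CM distribution); ``final_abs`` pools the
    per-polymer |final cm_rel| of all runs; ``delta`` is the separation
    statistic mean |cm_rel|.
    """

    condition: str
    n_runs: int
    final_cm: np.ndarray        # (n_runs,)
    final_abs: np.ndarray       # (2*n_runs,)
    delta: float
    delta_sd: float
    hist_edges: np.ndarray
    hist_mass: np.ndarray
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.hist_mass.sum() - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")

    @property
    def mean(self) -> float:
        return float(self.final_cm.mean())

    @property
    def std(self) -> float:
        return float(self.final_cm.std(ddof=1))

    def per_run_delta(self) -> np.ndarray:
        return self.final_abs.reshape(self.n_runs, 2).mean(axis=1)


def summarize_ensemble(runs, n_bins: int = 40) -> EnsembleSummary:
    """Aggregate a list of RunResult (see :mod:`minratchet.experiments`).

    Requires >= 2 runs with identical condition/configuration.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    cfgs = {tuple(sorted((k, repr(v)) for k, v in r.config.items())) for r in runs}
    if len(cfgs) != 1:
        raise ValueError("runs have mixed configurations")
    final_cm = np.array([r.final_cm_right for r in runs])
    final_abs = np.concatenate([r.final_abs for r in runs])
    hist, edges = np.histogram(final_cm, bins=n_bins, range=(-0.5, 0.5))
    mass = hist / hist.sum()
    return EnsembleSummary(
        condition=runs[0].condition,
        n_runs=len(runs),
        final_cm=final_cm,
        final_abs=final_abs,
        delta=float(final_abs.mean()),
        delta_sd=float(final_abs.std(ddof=1)),
        hist_edges=edges,
        hist_mass=mass,
        config=dict(runs[0].config),
    )


@dataclass
class ForceDistancePoint:
    applied_force: float        # kT per lattice unit of CM separation
    equilibrium_distance: float  # mean axial CM separation, lattice units
    uncertainty: float          # standard error over replicates
    n_samples: int

    def __post_init__(self):
        if self.applied_force < 0 or self.uncertainty < 0:
            raise ValueError("force and uncertainty must be >= 0")


def force_distance_curve(
    box,
    N,
    field_spec,
    forces,
    n_mcs_eq: int = 50_000,
    n_mcs_sample: int = 100_000,
    n_mcs_seg: int = 200_000,
    n_replicates: int = 4,
    seed: int = 0,
    interchain_exclusion: bool = True,
    record_every: int = 1_000,
):
    """Equilibrium CM separation under an attractive inter-ring force.

    For each force ``f`` the potential ``U = f * d`` (d = axial CM separation
    in lattice units, energies in kT) is added through a Metropolis layer.
    Each replicate first segregates force-free for ``n_mcs_seg`` MCS (the
    probe measures the force balance of the *separated* steady state), then
    re-equilibrates under the force and samples ``d`` for ``n_mcs_sample``
    MCS.  Returns a list of :class:`ForceDistancePoint`, one per force.
    """
    from .lattice import init_overlapping_rings, run_mcs

    points = []
    for f in forces:
        if f < 0:
            raise ValueError("forces must be >= 0")
        means = []
        for r in range(n_replicates):
            st = init_overlapping_rings(
                box, N, seed=seed + r, interchain_exclusion=interchain_exclusion
            )
            run_mcs(st, field_spec, n_mcs=n_mcs_seg)
            run_mcs(st, field_spec, n_mcs=n_mcs_eq, force=f)
            rec = run_mcs(st, field_spec, n_mcs=n_mcs_sample, force=f, record_every=record_every)
            d = np.abs(rec.cm_rel[:, 0] - rec.cm_rel[:, 1]) * box.Lx
            means.append(d.mean())
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else 0.0
        points.append(
            ForceDistancePoint(
                applied_force=float(f),
                equilibrium_distance=float(means.mean()),
                uncertainty=float(sem),
                n_samples=len(means) * (n_mcs_sample // record_every),
            )
        )
    return points
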