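"""Experiment orchestration: named conditions, ensembles, comparisons, fixtures.

Each condition name maps to exactly one simulator configuration.  Replicate
``i`` of an experiment uses seed ``seed_base + i``, so any run can be
reproduced in isolation.  The default tethering regime is weak and transient
(see :mod:`minratchet.tethering`); the oscillating and MinD-profile-driven
conditions use twice the static peak binding probability because the
oscillation concentrates the whole tether-site population on one pole each
half-cycle, doubling the local density relative to its time-average.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .lattice import ConfinementBox, init_overlapping_rings, run_mcs
from .min_profile import synthesize_oscillation
from .observables import EnsembleSummary, summarize_ensemble
from .tethering import TetherFieldSpec

__all__ = [
    "CONDITIONS",
    "ExperimentSpec",
    "RunResult",
    "condition_setup",
    "run_replicate",
    "run_ensemble",
    "run_experiment",
    "compare_conditions",
    "time_to_half_separation",
    "generate_fixtures",
]

#: peak binding probability of the static gradient (per MCS, at the pole)
P_STATIC = 0.01
#: peak binding probability of oscillating/profile-driven gradients (2x, see module docstring)
P_OSC = 0.02

CONDITIONS = (
    "no_tether",
    "uniform",
    "static_gradient",
    "oscillating_gradient",
    "mind_profile",
    "entropy_off_gradient",
    "dwell_x10",
)


def condition_setup(condition: str, steepness: float = 1.0):
    """Map a condition name to (TetherFieldSpec, interchain_exclusion)."""
    if condition == "no_tether":
        return TetherFieldSpec(mode="none"), True
    if condition == "uniform":
        return TetherFieldSpec(mode="uniform", p_max=P_STATIC), True
    if condition == "static_gradient":
        return TetherFieldSpec(mode="static_gradient", p_max=P_STATIC, steepness=steepness), True
    if condition == "oscillating_gradient":
        return (
            TetherFieldSpec(mode="oscillating_gradient", p_max=P_OSC, steepness=steepness),
            True,
        )
    if condition == "mind_profile":
        return (
            TetherFieldSpec(
                mode="mind_profile", p_max=P_OSC, profile=synthesize_oscillation()
            ),
            True,
        )
    if condition == "entropy_off_gradient":
        return TetherFieldSpec(mode="static_gradient", p_max=P_STATIC, steepness=steepness), False
    if condition == "dwell_x10":
        return (
            TetherFieldSpec(
                mode="static_gradient", p_max=P_STATIC, steepness=steepness, dwell_mean=1000.0
            ),
            True,
        )
    raise ValueError(f"unknown condition {condition!r}; choose from {CONDITIONS}")


@dataclass
class ExperimentSpec:
    """One reproducible ensemble experiment."""

    condition: str
    n_replicates: int = 24
    n_mcs: int = 500_000
    seed_base: int = 0
    box: tuple = (80, 10, 10)
    N: int = 80
    steepness: float = 1.0
    record_every: int = 5_000
    tail_records: int = 10     # trailing-window steady-state estimator
    output_dir: str | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_replicates < 1 or self.n_mcs < 0:
            raise ValueError("n_replicates >= 1 and n_mcs >= 0 required")

    def config_dict(self) -> dict:
        d = asdict(self)
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def replicate_seed(self, i: int) -> int:
        return self.seed_base + i


@dataclass
class RunResult:
    """Final-state statistics of one replicate."""

    condition: str
    seed: int
    labels: list
    final_cm_rel: np.ndarray     # (2,) signed, polymer order
    final_abs: np.ndarray        # (2,) |cm_rel| per polymer (trailing-window)
    initial_abs: np.ndarray      # (2,) |cm_rel| at t=0
    mcs_points: np.ndarray
    cm_rel_traj: np.ndarray      # (T, 2)
    config: dict = field(default_factory=dict)

    @property
    def final_cm_right(self) -> float:
        return float(self.final_cm_rel[self.labels.index("right")])

    @property
    def delta(self) -> float:
        return float(self.final_abs.mean())


def run_replicate(spec: ExperimentSpec, i: int) -> RunResult:
    from .observables import center_of_mass_rel

    field_spec, interchain = condition_setup(spec.condition, spec.steepness)
    box = ConfinementBox(*spec.box)
    st = init_overlapping_rings(
        box, spec.N, seed=spec.replicate_seed(i), interchain_exclusion=interchain
    )
    initial = np.array(
        [abs(center_of_mass_rel(st.polymer_positions(p), box)) for p in range(2)]
    )
    rec = run_mcs(st, field_spec, n_mcs=spec.n_mcs, record_every=spec.record_every)
    tail = min(spec.tail_records, len(rec.cm_rel)) or 1
    if len(rec.cm_rel) == 0:  # zero-length run
        traj = np.array([[center_of_mass_rel(st.polymer_positions(p), box) for p in range(2)]])
        pts = np.array([st.mcs_clock])
    else:
        traj = rec.cm_rel
        pts = rec.mcs_points
    final_abs = np.abs(traj[-tail:]).mean(axis=0)
    return RunResult(
        condition=spec.condition,
        seed=spec.replicate_seed(i),
        labels=list(st.labels),
        final_cm_rel=traj[-1].copy(),
        final_abs=final_abs,
        initial_abs=initial,
        mcs_points=pts,
        cm_rel_traj=traj,
        config=spec.config_dict(),
    )


def run_ensemble(spec: ExperimentSpec) -> tuple:
    """All replicates of one condition; returns (summary, runs)."""
    runs = [run_replicate(spec, i) for i in range(spec.n_replicates)]
    return summarize_ensemble(runs), runs


def run_experiment(spec: ExperimentSpec):
    """Run an ensemble and persist per-run CSVs, ensemble JSON and a manifest."""
    import pandas as pd

    if spec.output_dir is None:
        raise ValueError("output_dir required to persist an experiment")
    out = Path(spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary, runs = run_ensemble(spec)
    for i, r in enumerate(runs):
        df = pd.DataFrame(
            {
                "mcs": r.mcs_points,
                f"cm_rel_{r.labels[0]}": r.cm_rel_traj[:, 0],
                f"cm_rel_{r.labels[1]}": r.cm_rel_traj[:, 1],
            }
        )
        df.to_csv(out / f"run_{i:04d}.csv", index=False)
    # trailing-window drift diagnostic (non-blocking): mean |cm| drift across
    # the last two half-windows of the ensemble-average trajectory
    tail = max(2, spec.tail_records)
    mean_abs = np.abs(np.stack([r.cm_rel_traj for r in runs])).mean(axis=(0, 2))
    half = tail // 2
    drift = float(mean_abs[-half:].mean() - mean_abs[-tail:-half].mean()) if len(mean_abs) >= tail else float("nan")
    ens = {
        "condition": summary.condition,
        "n_runs": summary.n_runs,
        "delta": summary.delta,
        "delta_sd": summary.delta_sd,
        "mean_final_cm_right": summary.mean,
        "sd_final_cm_right": summary.std,
        "final_cm_right": summary.final_cm.tolist(),
        "final_abs": summary.final_abs.tolist(),
        "trailing_drift": drift,
    }
    (out / "ensemble.json").write_text(json.dumps(ens, indent=1))
    manifest = {
        "config": spec.config_dict(),
        "config_hash": spec.config_hash(),
        "seeds": [spec.replicate_seed(i) for i in range(spec.n_replicates)],
        "package_version": _version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary, runs


def _version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("minratchet")
    except PackageNotFoundError:
        return "unknown"


def time_to_half_separation(run: RunResult, threshold: float) -> float:
    """First MCS at which the run's mean |cm_rel| reaches ``threshold``;
    +inf if never."""
    m = np.abs(run.cm_rel_traj).mean(axis=1)
    idx = np.nonzero(m >= threshold)[0]
    return float(run.mcs_points[idx[0]]) if len(idx) else float("inf")


def compare_conditions(summaries, alpha: float = 0.05) -> dict:
    """Pairwise one-sided rank tests on the per-run separation statistic.

    All summaries must share the same base configuration apart from the
    condition itself.  For each ordered pair (a, b) reports the one-sided
    Mann-Whitney p-value for 'a separates more than b', the rank-biserial
    effect size, and significance at ``alpha``.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries")
    base_keys = ("n_mcs", "N", "box", "record_every")
    bases = {tuple((k, repr(s.config.get(k))) for k in base_keys) for s in summaries}
    if len(bases) != 1:
        raise ValueError("summaries have mismatched base configurations")
    report = {"alpha": alpha, "pairs": {}}
    for a in summaries:
        for b in summaries:
            if a is b:
                continue
            da, db = a.per_run_delta(), b.per_run_delta()
            res = stats.mannwhitneyu(da, db, alternative="greater")
            nb = res.statistic / (len(da) * len(db))
            report["pairs"][f"{a.condition}>{b.condition}"] = {
                "delta_a": float(da.mean()),
                "delta_b": float(db.mean()),
                "effect_rank_biserial": float(2 * nb - 1),
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
    return report


def generate_fixtures(outdir, seed: int = 0) -> dict:
    """Write the small deterministic test inputs; returns path map.

    Contents: a ring-of-4 state in a 6x6x6 box, a 2-frame MinD profile TSV,
    a two-Gaussian axial intensity profile CSV, and 100 synthetic Brownian
    focus tracks CSV.  Byte-identical for the same seed.
    """
    import pandas as pd

    from .lattice import SystemState, _grid_cycle
    from .min_profile import MinDProfileSeries, save_profile_series
    from .profile_metrics import simulate_focus_tracks

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    box = ConfinementBox(6, 6, 6)
    ring = _grid_cycle(2, 2, 1) * 2 + np.array([1, 1, 2])
    st = SystemState(box, [ring], rng=seed)
    run_mcs(st, None, n_mcs=100)
    st.validate()
    paths["ring4"] = out / "ring4_6x6x6.csv"
    st.to_table(paths["ring4"])

    bins = (np.arange(8) + 0.5) / 8
    series = MinDProfileSeries(
        frame_times=[0.0, 7.0],
        axial_bins=bins,
        intensities=np.vstack([np.linspace(1, 0.1, 8), np.linspace(0.1, 1, 8)]),
    )
    paths["min_profile"] = out / "min_profile_2frame.tsv"
    save_profile_series(series, paths["min_profile"])

    x = np.linspace(-2.5, 2.5, 101)
    y = np.exp(-((x - 1.0) ** 2) / (2 * 0.2**2)) + np.exp(-((x + 1.0) ** 2) / (2 * 0.2**2))
    paths["two_gaussian"] = out / "two_gaussian_profile.csv"
    pd.DataFrame({"position_um": x, "intensity": y}).to_csv(paths["two_gaussian"], index=False)

    tracks = simulate_focus_tracks(100, 50, dt=0.05, D0=0.05, seed=seed)
    rows = []
    for k, t in enumerate(tracks):
        for j in range(len(t.frame_times)):
            rows.append((k, t.frame_times[j], t.xy_positions[j, 0], t.xy_positions[j, 1]))
    paths["tracks"] = out / "focus_tracks.csv"
    pd.DataFrame(rows, columns=["track_id", "t", "x", "y"]).to_csv(paths["tracks"], index=False)
    return paths
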