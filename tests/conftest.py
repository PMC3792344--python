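"""Shared fixtures: cached simulation ensembles and small reference systems.

The heavyweight ensembles (steady-state segregation runs at the full
80 x 10 x 10 / N=80 geometry) are computed once per session and shared by
every test that reads them.  Seeds are fixed constants so the whole suite is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from minratchet.experiments import ExperimentSpec, run_ensemble

# one entry per experimental condition used by the steady-state tests:
# (condition, steepness, n_replicates, n_mcs, seed_base)
ENSEMBLE_PLAN = {
    "no_tether": ("no_tether", 1.0, 32, 500_000, 0),
    "static_gradient": ("static_gradient", 1.0, 32, 500_000, 100),
    "oscillating_gradient": ("oscillating_gradient", 1.0, 32, 500_000, 200),
    "mind_profile": ("mind_profile", 1.0, 24, 500_000, 300),
    "static_s2": ("static_gradient", 2.0, 24, 500_000, 400),
    "static_s05": ("static_gradient", 0.5, 24, 500_000, 500),
    "no_tether_short": ("no_tether", 1.0, 16, 200_000, 600),
    "uniform_short": ("uniform", 1.0, 16, 200_000, 700),
    "dwell_x10_short": ("dwell_x10", 1.0, 16, 200_000, 800),
    "entropy_off_short": ("entropy_off_gradient", 1.0, 16, 200_000, 900),
}

_cache = {}


def get_ensemble(name):
    """(summary, runs) for a named ensemble from ENSEMBLE_PLAN, cached."""
    if name not in _cache:
        condition, steep, n, n_mcs, seed = ENSEMBLE_PLAN[name]
        spec = ExperimentSpec(
            condition=condition,
            steepness=steep,
            n_replicates=n,
            n_mcs=n_mcs,
            seed_base=seed,
        )
        _cache[name] = run_ensemble(spec)
    return _cache[name]


@pytest.fixture(scope="session")
def ensembles():
    return get_ensemble


@pytest.fixture()
def small_ring_state():
    """A valid ring of 4 monomers in a 6x6x6 box."""
    from minratchet.lattice import ConfinementBox, SystemState, _grid_cycle

    ring = _grid_cycle(2, 2, 1) * 2 + np.array([1, 1, 2])
    return SystemState(ConfinementBox(6, 6, 6), [ring], rng=7)


@pytest.fixture(scope="session")
def default_state():
    """A freshly initialized two-ring state at the standard geometry."""
    from minratchet.lattice import ConfinementBox, init_overlapping_rings

    return init_overlapping_rings(ConfinementBox(), 80, seed=11)
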