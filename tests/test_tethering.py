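"""Tether fields: geometry, field shapes, bind/release dynamics."""

import numpy as np
import pytest
from scipy import stats

from minratchet.lattice import ConfinementBox, init_overlapping_rings, run_mcs
from minratchet.min_profile import synthesize_oscillation
from minratchet.tethering import (
    TetherFieldSpec,
    binding_probability,
    build_field_table,
    is_at_border,
    update_tethers,
)

BOX = ConfinementBox()


class TestBorder:
    @pytest.mark.parametrize(
        "pos,d_b,expect",
        [
            ((10, 0, 4), 1, True),     # touching the y=0 wall
            ((10, 9, 4), 1, True),     # touching the y=Ly wall
            ((10, 4, 4), 1, False),    # box center
            ((10, 4, 0), 1, True),     # touching the z=0 wall
            ((0, 4, 4), 1, False),     # touching only the x=0 pole cap
            ((79, 4, 4), 2, False),    # far pole cap, wider margin
            ((10, 1, 4), 2, True),     # one unit off the wall, d_b=2
            ((10, 2, 4), 2, False),
        ],
    )
    def test_lateral_eligibility(self, pos, d_b, expect):
        assert is_at_border(pos, BOX, d_b) == expect


class TestFieldShapes:
    def test_static_gradient_profile(self):
        spec = TetherFieldSpec(mode="static_gradient", p_max=0.4, steepness=1.0)
        assert binding_probability(40.0, 0, spec, BOX) == 0.0
        assert binding_probability(0.0, 0, spec, BOX) == pytest.approx(0.4)
        assert binding_probability(80.0, 0, spec, BOX) == pytest.approx(0.4)
        assert binding_probability(20.0, 0, spec, BOX) == pytest.approx(0.2)
        # steepness reshapes but keeps endpoints
        spec2 = TetherFieldSpec(mode="static_gradient", p_max=0.4, steepness=2.0)
        assert binding_probability(20.0, 0, spec2, BOX) == pytest.approx(0.4 * 0.25)
        assert binding_probability(0.0, 0, spec2, BOX) == pytest.approx(0.4)

    def test_uniform_constant(self):
        spec = TetherFieldSpec(mode="uniform", p_max=0.07)
        for x in (0.0, 13.0, 40.0, 80.0):
            for t in (0, 12345):
                assert binding_probability(x, t, spec, BOX) == 0.07

    def test_oscillating_masks_inactive_half(self):
        spec = TetherFieldSpec(mode="oscillating_gradient", p_max=0.2, period=1000)
        # first half-cycle: left pole active
        assert binding_probability(10.0, 0, spec, BOX) > 0
        assert binding_probability(70.0, 0, spec, BOX) == 0.0
        # second half-cycle: right pole active
        assert binding_probability(10.0, 1500, spec, BOX) == 0.0
        assert binding_probability(70.0, 1500, spec, BOX) > 0

    def test_oscillating_halves_equal_time_and_symmetric(self):
        spec = TetherFieldSpec(mode="oscillating_gradient", p_max=0.2, period=777)
        _, slot_of_mcs = build_field_table(spec, BOX)
        assert len(slot_of_mcs) == 2 * 777
        assert (slot_of_mcs == 0).sum() == (slot_of_mcs == 1).sum()
        # averaged over a full period the field is symmetric about mid-cell
        xs = np.linspace(0.5, 79.5, 80)
        avg = 0.5 * (
            np.array([binding_probability(x, 0, spec, BOX) for x in xs])
            + np.array([binding_probability(x, 777, spec, BOX) for x in xs])
        )
        assert np.allclose(avg, avg[::-1])

    def test_static_symmetric_about_midcell(self):
        spec = TetherFieldSpec(mode="static_gradient", p_max=0.3, steepness=1.7)
        xs = np.linspace(0.0, 80.0, 161)
        vals = np.array([binding_probability(x, 0, spec, BOX) for x in xs])
        assert np.allclose(vals, vals[::-1])

    def test_x_outside_box_rejected(self):
        spec = TetherFieldSpec(mode="uniform")
        with pytest.raises(ValueError):
            binding_probability(81.0, 0, spec, BOX)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TetherFieldSpec(mode="nope")
        with pytest.raises(ValueError):
            TetherFieldSpec(mode="uniform", p_max=1.5)
        with pytest.raises(ValueError):
            TetherFieldSpec(mode="mind_profile", profile=None)
        with pytest.raises(ValueError):
            TetherFieldSpec(mode="uniform", profile=synthesize_oscillation())


class TestDynamics:
    def test_mode_none_never_binds(self):
        st_ = init_overlapping_rings(BOX, 80, seed=5)
        rec = run_mcs(st_, TetherFieldSpec(mode="none"), n_mcs=2_000)
        assert rec.n_bind_events == 0
        assert not st_.tethered.any()

    def test_frozen_system_limit(self):
        # p=1 everywhere, border covers the whole box, enormous dwell:
        # every monomer binds at the first update and nothing moves again
        st_ = init_overlapping_rings(BOX, 80, seed=5)
        spec = TetherFieldSpec(
            mode="uniform", p_max=1.0, border_distance=10, dwell_mean=1e12
        )
        run_mcs(st_, spec, n_mcs=1)
        assert st_.tethered.all()
        frozen = st_.pos.copy()
        run_mcs(st_, spec, n_mcs=50)
        assert np.array_equal(st_.pos, frozen)

    def test_bound_monomer_position_fixed_until_release(self):
        # pure-Python reference path: bind everything, step the clock, and
        # check positions are pinned exactly while bound
        st_ = init_overlapping_rings(BOX, 80, seed=6)
        spec = TetherFieldSpec(mode="uniform", p_max=1.0, border_distance=10, dwell_mean=5.0)
        st_.mcs_clock = 1
        update_tethers(st_, spec)
        bound = st_.tethered.copy()
        assert bound.any()
        pinned = st_.pos[bound].copy()
        rec = run_mcs(st_, TetherFieldSpec(mode="none"), n_mcs=1)
        # released monomers may move afterwards, but for any monomer still
        # bound the position hash must be unchanged
        still = st_.tethered & bound
        assert np.array_equal(st_.pos[still], pinned[still[bound]])

    def test_dwell_time_mean_converges(self):
        # >= 1e4 binding events; drawn dwell mean within 5% of tau
        st_ = init_overlapping_rings(BOX, 80, seed=8)
        spec = TetherFieldSpec(mode="uniform", p_max=0.05, dwell_mean=40.0, border_distance=2)
        rec = run_mcs(st_, spec, n_mcs=30_000)
        assert rec.n_bind_events >= 10_000
        assert rec.mean_drawn_dwell == pytest.approx(40.0, rel=0.05)

    def test_binding_event_positions_match_field_shape(self):
        # empirical binding-x histogram vs analytic field, weighted by
        # occupancy of border monomers per axial position
        st_ = init_overlapping_rings(BOX, 80, seed=9)
        spec = TetherFieldSpec(mode="static_gradient", p_max=0.05, dwell_mean=20.0, border_distance=2)
        # long run to visit the whole axial range
        rec = run_mcs(st_, spec, n_mcs=60_000, log_events=200_000)
        obs = rec.bind_counts_x
        assert obs.sum() == rec.n_bind_events
        assert len(rec.events) == min(rec.n_bind_events, 200_000)
        # events recorded as (mcs, polymer, monomer, x)
        assert (rec.events[:, 3] >= 0).all() and (rec.events[:, 3] <= 79).all()
        # the field vanishes toward mid-cell: the central bins must be far
        # below the quarter-position bands despite higher polymer occupancy
        central = obs[38:42].mean()
        bands = np.r_[obs[15:26], obs[54:65]].mean()
        assert central < 0.2 * bands

    def test_p_zero_bitwise_identical_to_no_tether(self):
        # field evaluation must not consume randomness when p == 0
        run = {}
        for key, spec in {
            "none": TetherFieldSpec(mode="none"),
            "p0": TetherFieldSpec(mode="uniform", p_max=0.0),
            "grad0": TetherFieldSpec(mode="static_gradient", p_max=0.0),
        }.items():
            st_ = init_overlapping_rings(BOX, 80, seed=13)
            run_mcs(st_, spec, n_mcs=2_000)
            run[key] = st_.pos.copy()
        assert np.array_equal(run["none"], run["p0"])
        assert np.array_equal(run["none"], run["grad0"])
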