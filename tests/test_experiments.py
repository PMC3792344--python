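"""Experiment orchestration: conditions, persistence, comparisons, fixtures, CLI."""

import filecmp
import json

import numpy as np
import pytest
from click.testing import CliRunner

from minratchet.cli import main as cli_main
from minratchet.config import load_experiment_spec, save_experiment_spec
from minratchet.experiments import (
    CONDITIONS,
    ExperimentSpec,
    RunResult,
    compare_conditions,
    condition_setup,
    generate_fixtures,
    run_experiment,
    run_replicate,
    time_to_half_separation,
)
from minratchet.observables import summarize_ensemble


class TestConditions:
    def test_every_condition_maps(self):
        for c in CONDITIONS:
            spec, interchain = condition_setup(c)
            assert interchain == (c != "entropy_off_gradient")

    def test_dwell_x10_is_exactly_tenfold(self):
        base, _ = condition_setup("static_gradient")
        x10, _ = condition_setup("dwell_x10")
        assert x10.dwell_mean == 10 * base.dwell_mean

    def test_conditions_differ_only_in_implied_fields(self):
        base, _ = condition_setup("static_gradient")
        x10, _ = condition_setup("dwell_x10")
        eoff, eoff_inter = condition_setup("entropy_off_gradient")
        assert (x10.mode, x10.p_max, x10.steepness, x10.border_distance) == (
            base.mode,
            base.p_max,
            base.steepness,
            base.border_distance,
        )
        assert eoff == base and not eoff_inter

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_setup("banana")
        with pytest.raises(ValueError):
            ExperimentSpec(condition="banana")


class TestReplicates:
    def test_replicate_seeds_are_base_plus_index(self):
        spec = ExperimentSpec(condition="no_tether", seed_base=50, n_replicates=3, n_mcs=500)
        assert [spec.replicate_seed(i) for i in range(3)] == [50, 51, 52]

    def test_run_replicate_shapes(self):
        spec = ExperimentSpec(
            condition="static_gradient", n_replicates=1, n_mcs=2_000, record_every=500
        )
        r = run_replicate(spec, 0)
        assert r.cm_rel_traj.shape == (4, 2)
        assert sorted(r.labels) == ["left", "right"]
        assert r.initial_abs.max() <= 1.5 / 80

    def test_time_to_half_separation(self):
        r = RunResult(
            condition="no_tether",
            seed=0,
            labels=["left", "right"],
            final_cm_rel=np.array([-0.3, 0.3]),
            final_abs=np.array([0.3, 0.3]),
            initial_abs=np.zeros(2),
            mcs_points=np.array([100, 200, 300]),
            cm_rel_traj=np.array([[-0.05, 0.05], [-0.15, 0.15], [-0.3, 0.3]]),
            config={},
        )
        assert time_to_half_separation(r, 0.1) == 200
        assert time_to_half_separation(r, 0.9) == np.inf


class TestPersistence:
    def test_experiment_outputs_and_determinism(self, tmp_path):
        spec = ExperimentSpec(
            condition="no_tether",
            n_replicates=2,
            n_mcs=1_000,
            record_every=250,
            seed_base=4,
            output_dir=str(tmp_path / "a"),
        )
        run_experiment(spec)
        spec.output_dir = str(tmp_path / "b")
        run_experiment(spec)
        for name in ["run_0000.csv", "run_0001.csv", "ensemble.json", "manifest.json"]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["seeds"] == [4, 5]
        assert manifest["config_hash"]
        ens = json.loads((tmp_path / "a" / "ensemble.json").read_text())
        assert ens["n_runs"] == 2

    def test_config_round_trip(self, tmp_path):
        spec = ExperimentSpec(condition="uniform", n_replicates=3, n_mcs=123, seed_base=9)
        p = tmp_path / "cfg.yaml"
        save_experiment_spec(spec, p)
        back = load_experiment_spec(p)
        assert back == spec

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("condition: no_tether\nbanana: 1\n")
        with pytest.raises(ValueError, match="banana"):
            load_experiment_spec(p)


class TestCompare:
    def _summary(self, finals, condition):
        runs = []
        for i, f in enumerate(finals):
            runs.append(
                RunResult(
                    condition=condition,
                    seed=i,
                    labels=["left", "right"],
                    final_cm_rel=np.array([-f, f]),
                    final_abs=np.array([abs(f), abs(f)]),
                    initial_abs=np.zeros(2),
                    mcs_points=np.array([0]),
                    cm_rel_traj=np.array([[-f, f]]),
                    config={"n_mcs": 100, "N": 80, "box": (80, 10, 10), "record_every": 10},
                )
            )
        return summarize_ensemble(runs)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(0)
        a = self._summary(0.30 + 0.02 * rng.standard_normal(20), "static_gradient")
        b = self._summary(0.20 + 0.02 * rng.standard_normal(20), "no_tether")
        rep = compare_conditions([a, b])
        assert rep["pairs"]["static_gradient>no_tether"]["significant"]
        assert not rep["pairs"]["no_tether>static_gradient"]["significant"]
        assert rep["pairs"]["static_gradient>no_tether"]["effect_rank_biserial"] > 0.9

    def test_identical_ensembles_not_significant(self):
        rng = np.random.default_rng(1)
        vals = 0.25 + 0.02 * rng.standard_normal(20)
        a = self._summary(vals, "no_tether")
        b = self._summary(vals.copy(), "uniform")
        rep = compare_conditions([a, b])
        assert not rep["pairs"]["no_tether>uniform"]["significant"]

    def test_mismatched_base_config_rejected(self):
        a = self._summary([0.1, 0.2, 0.3], "no_tether")
        b = self._summary([0.1, 0.2, 0.3], "uniform")
        b.config["n_mcs"] = 999
        with pytest.raises(ValueError, match="mismatch"):
            compare_conditions([a, b])


class TestFixtures:
    def test_regenerate_byte_identical(self, tmp_path):
        pa = generate_fixtures(tmp_path / "a", seed=2)
        pb = generate_fixtures(tmp_path / "b", seed=2)
        for k in pa:
            assert filecmp.cmp(pa[k], pb[k], shallow=False), k

    def test_fixtures_pass_their_validators(self, tmp_path):
        from minratchet.lattice import SystemState, allowed_bond_set
        from minratchet.min_profile import load_profile_series
        from minratchet.profile_metrics import FocusTrack, IntensityProfile1D
        import pandas as pd

        paths = generate_fixtures(tmp_path, seed=2)
        st_ = SystemState.from_table(paths["ring4"])
        st_.validate()
        # ring-of-4 bonds are each in the allowed set (hand-checkable table)
        ring = st_.polymer_positions(0)
        bonds = {tuple(b) for b in (np.roll(ring, -1, axis=0) - ring)}
        assert bonds <= allowed_bond_set()
        load_profile_series(paths["min_profile"])
        df = pd.read_csv(paths["two_gaussian"])
        IntensityProfile1D(df["position_um"], df["intensity"])
        tr = pd.read_csv(paths["tracks"])
        assert tr["track_id"].nunique() == 100
        g = tr[tr["track_id"] == 0]
        FocusTrack(g["t"].to_numpy(), g[["x", "y"]].to_numpy())


class TestCli:
    def test_simulate_and_metrics_flow(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            [
                "simulate",
                "--condition",
                "no_tether",
                "--n-mcs",
                "1000",
                "--record-every",
                "250",
                "--out",
                str(tmp_path / "traj.csv"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "traj.csv").exists()

        res = runner.invoke(
            cli_main, ["fixtures", "--seed", "1", "--out", str(tmp_path / "fix")]
        )
        assert res.exit_code == 0, res.output

        res = runner.invoke(
            cli_main,
            [
                "metrics",
                "separation",
                "--profile",
                str(tmp_path / "fix" / "two_gaussian_profile.csv"),
            ],
        )
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["n_nucleoids"] == 2 and out["D"] == pytest.approx(2.0, abs=0.05)

        res = runner.invoke(
            cli_main,
            ["metrics", "msd", "--tracks", str(tmp_path / "fix" / "focus_tracks.csv")],
        )
        assert res.exit_code == 0, res.output
        out = json.loads(res.output)
        assert out["D_app"] == pytest.approx(0.05, rel=0.2)

    def test_min_profile_synth_round_trip(self, tmp_path):
        from minratchet.min_profile import load_profile_series

        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["min-profile", "synth", "--n-frames", "16", "--out", str(tmp_path / "p.tsv")],
        )
        assert res.exit_code == 0, res.output
        series = load_profile_series(tmp_path / "p.tsv")
        assert series.n_frames == 16
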