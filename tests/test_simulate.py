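"""Integrator correctness against closed forms, scans, and steady states."""

import numpy as np
import pytest

from cd4sim.model import ModelDefinition, RateLaw, Reaction, Species
from cd4sim.protocols import CANONICAL_RECIPES
from cd4sim.simulate import (
    parameter_scan,
    scan_time_course,
    simulate_time_course,
    steady_state,
)

from conftest import make_decay_toy, make_source_sink_toy


class TestClosedFormOracles:
    def test_linear_decay_matches_exponential(self):
        # A -> B with k = 1: B(t) = 1 - e^-t, so B(1 h) = 0.632...
        toy = make_decay_toy(k=1.0)
        traj = simulate_time_course(toy, {}, t_end=5.0, n_points=201)
        exact_B = 1.0 - np.exp(-traj.time)
        assert np.max(np.abs(traj["B"] - exact_B)) < 1e-6
        assert traj.at_time(1.0)["B"] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-6)

    def test_source_sink_matches_relaxation(self):
        # dX/dt = k_in*S - k_out*X: X(t) = X*(1 - e^(-k_out t))
        toy = make_source_sink_toy(k_in=0.7, k_out=0.35)
        traj = simulate_time_course(toy, {"S": 1.0}, t_end=30.0, n_points=301)
        xstar = 0.7 / 0.35
        exact = xstar * (1.0 - np.exp(-0.35 * traj.time))
        assert np.max(np.abs(traj["X"] - exact)) < 1e-6


class TestTrajectoryContract:
    def test_time_strictly_increasing_and_nonnegative(self, reference_model):
        traj = simulate_time_course(reference_model, CANONICAL_RECIPES["Th17"], n_points=200)
        assert np.all(np.diff(traj.time) > 0)
        assert traj.states.min() > -1e-9

    def test_boundary_levels_recorded_and_clamped(self, source_sink_toy):
        traj = simulate_time_course(source_sink_toy, {"S": 2.0}, t_end=60.0, n_points=50)
        assert traj.boundary_levels == {"S": 2.0}
        # doubling the source doubles the steady level
        assert traj.final_state["X"] == pytest.approx(2.0 * 0.7 / 0.35, rel=1e-5)

    def test_rejects_dynamic_species_in_recipe(self, source_sink_toy):
        with pytest.raises(ValueError, match="boundary"):
            simulate_time_course(source_sink_toy, {"X": 1.0}, t_end=1.0)

    def test_zero_input_leaves_baseline(self, reference_model):
        # no driving cytokines: master regulators stay at (decaying) baseline
        traj = simulate_time_course(reference_model, {}, n_points=100)
        end = traj.final_state
        for tf in ("TBET", "GATA3", "RORGT", "FOXP3"):
            assert end[tf] <= 0.01

    def test_tidy_export(self, tmp_path, source_sink_toy):
        traj = simulate_time_course(source_sink_toy, {"S": 1.0}, t_end=5.0, n_points=10)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        import pandas as pd

        df = pd.read_csv(out)
        assert list(df.columns) == ["time", "species", "level"]
        assert set(df["species"]) == {"X"}
        assert len(df) == 10


class TestToleranceRobustness:
    def test_halved_tolerances_shift_endpoints_under_0p1_percent(self, reference_model):
        recipe = CANONICAL_RECIPES["Th17"]
        a = simulate_time_course(reference_model, recipe, n_points=50)
        b = simulate_time_course(
            reference_model, recipe, n_points=50, rtol=0.5e-8, atol=0.5e-10
        )
        ref = np.abs(a.states[-1]) + 1e-9
        assert np.max(np.abs(a.states[-1] - b.states[-1]) / ref) < 1e-3


class TestSteadyState:
    def test_source_sink_closed_form(self):
        toy = make_source_sink_toy(k_in=0.7, k_out=0.35)
        ss = steady_state(toy, {"S": 1.0})
        assert ss["X"] == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("lineage", ["Th1", "Th2", "Th17", "iTreg"])
    def test_agrees_with_long_time_course(self, reference_model, lineage):
        recipe = CANONICAL_RECIPES[lineage]
        ss = steady_state(reference_model, recipe)
        traj = simulate_time_course(reference_model, recipe, t_end=3000.0, n_points=50)
        end = traj.final_state
        for sid, value in ss.items():
            assert value == pytest.approx(end[sid], rel=1e-4, abs=1e-6)


class TestScans:
    def test_scan_over_disconnected_parameter_is_constant(self, reference_model):
        # the IL-21 receptor arm is quiescent under the Th17 recipe
        scan = parameter_scan(
            reference_model,
            CANONICAL_RECIPES["Th17"],
            "r08_IL21R_act_vmax",
            [0.5, 1.0, 2.0],
            ["RORGT", "IL17_s"],
            n_points=60,
        )
        assert np.allclose(scan.readouts["RORGT"], scan.readouts["RORGT"].iloc[0])
        assert not scan.failures

    def test_single_point_scan_equals_time_course(self, reference_model):
        recipe = CANONICAL_RECIPES["Th17"]
        scan = parameter_scan(
            reference_model, recipe, "PIO", [0.0], ["RORGT", "FOXP3"], n_points=60
        )
        traj = simulate_time_course(reference_model, recipe, n_points=60)
        end = traj.final_state
        assert scan.readouts["RORGT"].iloc[0] == pytest.approx(end["RORGT"], rel=1e-9)
        assert scan.readouts["FOXP3"].iloc[0] == pytest.approx(end["FOXP3"], rel=1e-9)

    def test_duplicate_grid_values_give_identical_trajectories(self, reference_model):
        trajs = scan_time_course(
            reference_model, CANONICAL_RECIPES["Th17"], "PIO", [1.0, 1.0],
            t_end=40.0, n_points=50,
        )
        assert len(trajs) == 2
        assert np.array_equal(trajs[0].states, trajs[1].states)

    def test_output_count_matches_grid(self, reference_model):
        grid = [0.0, 0.5, 1.0]
        trajs = scan_time_course(
            reference_model, CANONICAL_RECIPES["Th17"], "PIO", grid,
            t_end=20.0, n_points=30,
        )
        assert len(trajs) == len(grid)

    def test_empty_grid_rejected(self, reference_model):
        with pytest.raises(ValueError):
            parameter_scan(reference_model, {}, "PIO", [], ["RORGT"])
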