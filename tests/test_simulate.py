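"""Tests for dosing schedules and the segmented ODE integrator."""

import numpy as np
import pytest

from swarmsafe.models import (
    BlamDimensionlessParams,
    SimplifiedParams,
    SwarmbotState,
    TransportParams,
)
from swarmsafe.simulate import DosingSchedule, Trajectory, dilution_rate_at, simulate


class TestDosingSchedule:
    def test_static_is_zero_everywhere(self):
        sched = DosingSchedule.static(i_s=5.0)
        assert dilution_rate_at(sched, 0.0) == 0.0
        assert dilution_rate_at(sched, 123.4) == 0.0
        assert sched.mean_rate == 0.0

    def test_experimental_schedule_gives_two_per_hour(self):
        """4 ul/min for 5 of every 30 min into a ~20 ul device: the
        during-pulse rate is 0.2/min and the effective dilution rate 2/h."""
        sched = DosingSchedule.from_flow(
            flow_ul_per_min=4.0,
            pulse_minutes=5.0,
            delay_minutes=25.0,
            device_volume_ul=20.0,
            mu_max_per_hour=1.0,
        )
        # dimensionless time unit is one hour at mu_max = 1/h
        assert sched.d_pulse == pytest.approx(0.2 * 60.0)  # 0.2/min as per-hour
        assert sched.mean_rate == pytest.approx(2.0)

    def test_pulse_window_is_half_open(self):
        sched = DosingSchedule(mode="pulsing", d_pulse=3.0, pulse_duration=0.1, period=0.5)
        assert dilution_rate_at(sched, 0.0) == 3.0  # pulse-start side wins
        assert dilution_rate_at(sched, 0.1) == 0.0
        assert dilution_rate_at(sched, 0.5) == 3.0
        assert dilution_rate_at(sched, 0.4999999) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dilution_rate_at(DosingSchedule.static(), -1.0)

    def test_invalid_pulse_shape_rejected(self):
        with pytest.raises(ValueError):
            DosingSchedule(mode="pulsing", d_pulse=1.0, pulse_duration=0.6, period=0.5)

    def test_boundaries_cover_every_cycle(self):
        sched = DosingSchedule(mode="pulsing", d_pulse=1.0, pulse_duration=0.1, period=0.5)
        edges = sched.boundaries(1.2)
        assert list(edges) == pytest.approx([0.1, 0.5, 0.6, 1.0, 1.1])


class TestSimulate:
    def test_extinction_branch_below_threshold(self, ref_params):
        traj = simulate("simplified", [0.4], ref_params, horizon=200.0)
        assert traj.terminal[0] < 1e-3

    def test_survival_branch_above_threshold(self, ref_params):
        from swarmsafe.steady_state import find_steady_states

        upper = find_steady_states(ref_params).values[2]
        traj = simulate("simplified", [0.8], ref_params, horizon=200.0)
        assert traj.terminal[0] == pytest.approx(upper, abs=1e-3)

    def test_trajectory_invariants(self, ref_params):
        traj = simulate("simplified", [0.7], ref_params, horizon=10.0, n_samples=50)
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.states >= 0)
        assert traj.states.shape[0] == traj.times.shape[0]

    def test_inadmissible_initial_state_reported(self, ref_params):
        with pytest.raises(ValueError):
            simulate("simplified", [-0.2], ref_params, horizon=1.0)

    def test_segmented_grid_contains_pulse_boundaries(self, blam_params, transport):
        sched = DosingSchedule(
            mode="pulsing", d_pulse=1.2, pulse_duration=1 / 12, period=0.5, i_s=5.0
        )
        traj = simulate(
            "swarmbot",
            SwarmbotState(n1=0.3, s1=5.0, s2=5.0),
            (blam_params, transport),
            schedule=sched,
            horizon=2.0,
        )
        for edge in sched.boundaries(2.0):
            assert np.any(np.isclose(traj.times, edge, atol=1e-12))

    def test_static_schedule_matches_unsegmented_run(self, blam_params, transport):
        """With a smooth (static) schedule the segmentation machinery must
        be a no-op up to solver tolerance."""
        y0 = SwarmbotState(n1=0.3, s1=5.0, a1=0.2, s2=5.0, a2=0.2)
        a = simulate("swarmbot", y0, (blam_params, transport),
                     schedule=DosingSchedule.static(), horizon=5.0)
        b = simulate("swarmbot", y0, (blam_params, transport), schedule=None, horizon=5.0)
        assert np.allclose(a.terminal, b.terminal, atol=1e-8)

    def test_mass_constant_with_reactions_and_dosing_off(self):
        """No nutrient, no BlaM, no dosing: transport only redistributes, so
        the volume-weighted total of each species stays fixed."""
        p = BlamDimensionlessParams()
        tp = TransportParams(f_n=0.05, f_s=0.9, f_a=0.6, f_b=0.3, v_ratio=7.0)
        y0 = SwarmbotState(n1=0.8, s1=0.0, a1=1.3, b1=0.0, n2=0.1, s2=0.0, a2=0.2, b2=0.0)
        traj = simulate("swarmbot", y0, (p, tp), horizon=20.0)
        for i, j in ((0, 4), (2, 6)):
            total = traj.states[:, i] + tp.v_ratio * traj.states[:, j]
            assert np.max(np.abs(total - total[0])) < 1e-9 * max(1.0, total[0])

    def test_tolerance_refinement_stability(self, ref_params):
        base = simulate("simplified", [0.7], ref_params, horizon=30.0)
        tight = simulate("simplified", [0.7], ref_params, horizon=30.0,
                         rtol=5e-9, atol=5e-11)
        assert abs(base.terminal[0] - tight.terminal[0]) < 1e-6

    def test_pulsing_only_for_two_compartment_blam(self, ref_params):
        sched = DosingSchedule(mode="pulsing", d_pulse=1.0, pulse_duration=0.1, period=0.5)
        with pytest.raises(ValueError):
            simulate("simplified", [0.5], ref_params, schedule=sched, horizon=1.0)


class TestTrajectoryContainer:
    def test_tidy_export_round_trip(self, ref_params, tmp_path):
        traj = simulate("simplified", [0.7], ref_params, horizon=5.0, n_samples=20)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        import pandas as pd

        frame = pd.read_csv(out)
        assert set(frame.columns) == {"time", "compartment", "species", "value"}
        assert (tmp_path / "traj.meta.json").exists()

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0, 1.0]), states=np.zeros((3, 1)),
                       model_id="simplified")

    def test_density_accessor_names_compartments(self, blam_params, transport):
        traj = simulate("swarmbot", SwarmbotState(n1=0.2, s1=2.0, s2=2.0),
                        (blam_params, transport), horizon=1.0)
        assert traj.density("inside")[0] == pytest.approx(0.2)
        with pytest.raises(KeyError):
            traj.density("nowhere")
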