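"""Coupled simulation: packing, validation, determinism, engine agreement."""

import numpy as np
import pytest

import hhsync as hs
from hhsync import (ConfigError, FunnelViolationError, HHState, Trajectory,
                    assemble_state, default_config, global_derivative, run,
                    unpack_state, validate_config)

SHORT = {"sim": {"dt": 1e-5, "duration": 0.01, "record_every": 10}}


class TestStatePacking:
    def test_round_trip_identity(self):
        m = HHState(0.1, 0.2, 0.0, 0.2)
        s = HHState(0.3, 0.1, 0.2, 0.0)
        w = np.arange(5.0)
        m2, s2, w2 = unpack_state(assemble_state(m, s, w))
        assert m2 == m and s2 == s
        np.testing.assert_array_equal(w2, w)

    def test_global_dimension_with_study_network(self):
        flat = assemble_state(HHState(0, 0, 0, 0), HHState(0, 0, 0, 0), np.zeros(441))
        assert flat.shape == (449,)

    def test_distinct_states_pack_distinctly(self):
        a = assemble_state(HHState(1, 0, 0, 0), HHState(0, 0, 0, 0), [0.0])
        b = assemble_state(HHState(0, 0, 0, 0), HHState(1, 0, 0, 0), [0.0])
        assert not np.array_equal(a, b)


class TestConfigValidation:
    def test_empty_config_resolves_to_study_defaults(self, default_cfg):
        c = default_cfg
        assert c.performance.beta0 == 0.3 and c.performance.beta_inf == 0.02
        assert c.performance.kappa == 0.6 and c.performance.H == 0.9
        assert c.rbf_nodes_per_dim == 21 and c.rbf_width == 0.25
        assert c.gains.k1 + c.gains.k2 == 4.0
        assert c.rbf_adapt_gain == 1.0 and c.rbf_leak == 1e-3
        assert c.tmas_master.mf == 100.0 and c.tmas_slave.mf == 104.0
        assert c.x_master0 == (0.1, 0.2, 0.0, 0.2)
        assert c.x_slave0 == (0.3, 0.1, 0.2, 0.0)
        assert c.initial_error == pytest.approx(0.2, abs=1e-15)

    def test_overshoot_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError, match="H"):
            validate_config({"performance": {"H": 1.2}})

    def test_infeasible_initial_error_rejected(self):
        """The funnel guarantee needs e(0) strictly inside the envelope."""
        with pytest.raises(ConfigError, match="funnel"):
            validate_config({"initial": {"x_slave": [0.5, 0.1, 0.2, 0.0]}})
        # ... but an open-loop run has no such constraint
        cfg = validate_config({"controller": {"type": "none"},
                               "initial": {"x_slave": [0.5, 0.1, 0.2, 0.0]}})
        assert cfg.initial_error == pytest.approx(0.4)

    def test_problems_are_aggregated(self):
        with pytest.raises(ConfigError) as exc:
            validate_config({"performance": {"H": 2.0},
                             "rbf": {"width": -1.0},
                             "sim": {"dt": -1e-5}})
        assert len(exc.value.problems) >= 3

    def test_slave_capacitance_switch(self):
        cs = validate_config({})
        cm = validate_config({"slave_capacitance": "CM"})
        assert cs.slave.C == 0.9 and cm.slave.C == 1.0

    def test_error_sign_switch_flips_branch(self):
        flipped = validate_config({"error_sign": "master_minus_slave",
                                   "controller": {"type": "none"}})
        assert flipped.initial_error == pytest.approx(-0.2)
        assert flipped.branch is hs.FunnelBranch.NONPOSITIVE


class TestDeterminismAndEngines:
    def test_identical_configs_identical_trajectories(self):
        a = run(SHORT)
        b = run(SHORT)
        np.testing.assert_array_equal(a.data.to_numpy(), b.data.to_numpy())

    def test_python_and_compiled_engines_agree(self):
        over = {"sim": {"dt": 1e-5, "duration": 2e-3, "record_every": 1}}
        a = run(over, engine="numba")
        b = run(over, engine="python")
        np.testing.assert_array_equal(a.data.to_numpy(), b.data.to_numpy())

    def test_kernel_matches_composed_reference_derivative(self):
        """One explicit-Euler step of the engine equals the state advanced
        with the pure module-composed global derivative."""
        cfg = validate_config({"sim": {"dt": 1e-6, "duration": 2e-6,
                                       "record_every": 1, "solver": "euler"}})
        traj = run(cfg)
        y0 = np.concatenate([cfg.x_master0, cfg.x_slave0, np.zeros(441)])
        expected = y0 + cfg.sim.dt * global_derivative(y0, 0.0, cfg)
        got = traj.data.iloc[1][["V_m", "n_m", "m_m", "h_m",
                                 "V_s", "n_s", "m_s", "h_s"]].to_numpy()
        np.testing.assert_allclose(got, expected[:8], rtol=1e-12, atol=1e-15)

    def test_euler_solver_available_for_cross_checks(self):
        traj = run({"sim": {"dt": 1e-6, "duration": 1e-4, "record_every": 10,
                            "solver": "euler"}})
        assert traj.completed


class TestClosedLoopStructure:
    def test_twin_neurons_never_desynchronize(self):
        """Identical parameters, stimuli and initial states with no control
        give e(t) = 0 identically (symmetric vector fields)."""
        cfg = default_config()
        traj = run({"controller": {"type": "none"},
                    "slave": cfg["master"],
                    "mf_slave": cfg["mf_master"],
                    "initial": {"x_slave": cfg["initial"]["x_master"]},
                    **SHORT})
        np.testing.assert_array_equal(traj.e, 0.0)

    def test_master_is_isolated_from_controller(self):
        """The master neuron's trajectory is bit-identical whatever the
        slave-side controller does (unidirectional coupling)."""
        cols = ["V_m", "n_m", "m_m", "h_m", "i_ext_m"]
        ref = run({"controller": {"type": "none"}, **SHORT}).data[cols]
        for ctype in ("ppc", "observer", "mec"):
            other = run({"controller": {"type": ctype}, **SHORT}).data[cols]
            np.testing.assert_array_equal(ref.to_numpy(), other.to_numpy())

    def test_time_scale_rescales_stimulus_clock(self):
        a = run({"controller": {"type": "none"},
                 "sim": {"dt": 1e-5, "duration": 5e-3, "record_every": 1}})
        b = run({"controller": {"type": "none"},
                 "sim": {"dt": 5e-6, "duration": 2.5e-3, "record_every": 1,
                         "time_scale": 2.0}})
        np.testing.assert_allclose(a.i_ext_m, b.i_ext_m, rtol=1e-12)

    def test_funnel_violation_reports_partial_trajectory(self):
        """The lagged finite-difference gain correction destabilizes the
        wall approach: the run aborts with a structured violation instead
        of silently clipping the error."""
        over = {"controller": {"phi_dot_mode": "fd"},
                "sim": {"dt": 1e-5, "duration": 0.2, "record_every": 20}}
        traj = run(over)
        assert traj.status == "funnel_violation"
        assert 0.0 < traj.t_stop < 0.2
        assert len(traj) > 10  # diagnostics retained
        with pytest.raises(FunnelViolationError) as exc:
            run(over, raise_on_violation=True)
        assert exc.value.trajectory.status == "funnel_violation"

    def test_rk4_self_convergence_on_short_window(self):
        """Halving the step changes the final error by far less than the
        1e-6 bound expected of a fourth-order scheme at the default step."""
        final = []
        for dt in (1e-5, 5e-6):
            traj = run({"sim": {"dt": dt, "duration": 0.05,
                                "record_every": int(0.05 / dt)}})
            final.append(traj.e[-1])
        assert abs(final[0] - final[1]) < 1e-6


class TestTrajectoryContainer:
    def test_csv_round_trip_with_sidecar(self, tmp_path):
        traj = run(SHORT)
        path = tmp_path / "run.csv"
        traj.to_csv(path)
        from hhsync.cli import _traj_from_csv
        back = _traj_from_csv(path)
        np.testing.assert_allclose(back.data.to_numpy(), traj.data.to_numpy(),
                                   rtol=0, atol=1e-12)
        assert back.status == traj.status
        assert back.metadata["performance"]["beta0"] == 0.3

    def test_decimation(self):
        traj = run(SHORT)
        half = traj.decimate(2)
        assert len(half) == (len(traj) + 1) // 2
        np.testing.assert_array_equal(half.t, traj.t[::2])

    def test_degenerate_frames_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            Trajectory(pd.DataFrame({"t": []}), "completed", 0.0)
        with pytest.raises(ValueError):
            Trajectory(pd.DataFrame({"t": [0.0, 0.0]}), "completed", 0.0)
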