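"""Simulator unit tests: conductance algebra, current bookkeeping,
stimulus delivery, determinism."""

import numpy as np
import pytest

from ipsctwin import _kernel as kernel
from ipsctwin.constants import (
    BASELINE_VECTOR,
    CONDUCTANCE_NAMES,
    REFERENCE_INITIAL_STATE,
)
from ipsctwin.evaluation import detect_upstrokes, extract_features
from ipsctwin.model_core import (
    BlockRangeError,
    ConductanceSet,
    SimulationTimeout,
    SolverSettings,
    StimulusSpec,
    Trajectory,
    UnknownCurrentError,
    apply_block,
    currents,
    derivatives,
    simulate,
)
from ipsctwin.protocols import Condition, extract_window

from conftest import TEST_DURATION_S


class TestConductanceSet:
    def test_baseline_has_the_16_canonical_parameters(self):
        cs = ConductanceSet.baseline()
        assert set(cs.multipliers) == set(CONDUCTANCE_NAMES)
        assert len(cs.multipliers) == 16

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_multiplier_rejected(self, bad):
        with pytest.raises(ValueError, match="must be > 0"):
            ConductanceSet.baseline().replace(G_Kr=bad)

    def test_wrong_name_set_rejected(self):
        with pytest.raises(ValueError, match="16 canonical"):
            ConductanceSet({"G_Kr": 1.0})

    def test_vector_round_trip(self):
        vec = np.linspace(0.5, 2.0, 16)
        assert np.array_equal(ConductanceSet.from_vector(vec).to_vector(), vec)


class TestApplyBlock:
    def test_empty_blocks_is_identity(self):
        cs = ConductanceSet.baseline()
        assert apply_block(cs, {}).multipliers == cs.multipliers

    def test_full_ikr_block_zeroes_gkr(self):
        out = apply_block(ConductanceSet.baseline(), {"I_Kr": 1.0})
        assert out["G_Kr"] < 1e-300  # numerically zero, kept positive

    def test_half_ical_block_arithmetic(self):
        cs = ConductanceSet.baseline().replace(G_CaL=1.2)
        assert apply_block(cs, {"I_CaL": 0.5})["G_CaL"] == pytest.approx(0.6)

    def test_input_untouched(self):
        cs = ConductanceSet.baseline()
        apply_block(cs, {"I_Kr": 0.3})
        assert cs["G_Kr"] == 1.0

    def test_unknown_current_named_in_error(self):
        with pytest.raises(UnknownCurrentError, match="I_bogus"):
            apply_block(ConductanceSet.baseline(), {"I_bogus": 0.1})

    @pytest.mark.parametrize("frac", [-0.1, 1.5])
    def test_fraction_out_of_range(self, frac):
        with pytest.raises(BlockRangeError):
            apply_block(ConductanceSet.baseline(), {"I_Kr": frac})


class TestDerivatives:
    def setup_method(self):
        self.cond = Condition("physio", cao_mM=1.8, duration_s=1.0)
        self.state = REFERENCE_INITIAL_STATE.copy()

    def test_baseline_multipliers_reproduce_raw_kernel_rhs(self):
        """All multipliers 1, no blocks/stimulus: identical to the baseline
        model right-hand side at the same state."""
        p = np.zeros(kernel.N_PARAMS)
        p[:16] = BASELINE_VECTOR
        p[kernel.IP_CAO], p[kernel.IP_NAO], p[kernel.IP_KO] = 1.8, 140.0, 5.4
        expected = kernel.rhs(0.0, self.state, p)
        got = derivatives(self.state, 0.0, ConductanceSet.baseline(),
                          self.cond)
        assert np.array_equal(got, expected)

    def test_ikr_block_scales_only_ikr(self):
        """A 30% IKr block scales the IKr term by 0.70 and leaves every
        other current bit-identical."""
        cs = ConductanceSet.baseline()
        free = currents(self.state, 0.0, cs, self.cond)
        blocked_cond = self.cond.with_blocks({"I_Kr": 0.30})
        blk = currents(self.state, 0.0, cs, blocked_cond)
        assert blk["I_Kr"] == pytest.approx(0.7 * free["I_Kr"], rel=1e-12)
        for name in free:
            if name != "I_Kr":
                assert blk[name] == free[name]

    @pytest.mark.parametrize("v_offset", [0.0, 30.0, -15.0])
    def test_charge_bookkeeping(self, v_offset):
        """The sum of all membrane ionic currents plus the stimulus equals
        -dVm/dt (Cm-normalized units) at any state."""
        state = self.state.copy()
        state[0] += v_offset
        stim = StimulusSpec.paced(1.0)
        cur = currents(state, 0.5, ConductanceSet.baseline(), self.cond,
                       stim=stim)
        dv = derivatives(state, 0.5, ConductanceSet.baseline(), self.cond,
                         stim=stim)[0]
        membrane = sum(v for k, v in cur.items() if not k.startswith("J_"))
        assert membrane == pytest.approx(-dv, rel=1e-12, abs=1e-12)
        assert cur["I_stim"] == -60.0  # inside the first 1 ms pulse


class TestSimulate:
    def test_tiny_duration_keeps_state(self, baseline_cell, solver):
        cond = Condition("physio", duration_s=0.001)
        traj = simulate(baseline_cell, cond, solver=solver)
        assert abs(traj.vm[-1] - traj.vm[0]) < 0.1

    def test_determinism(self, baseline_cell, solver):
        cond = Condition("physio", duration_s=3.0)
        a = simulate(baseline_cell, cond, solver=solver)
        b = simulate(baseline_cell, cond, solver=solver)
        assert np.array_equal(a.states, b.states)

    def test_paced_one_upstroke_per_period(self, baseline_cell, solver):
        cond = Condition("paced1hz", pacing=StimulusSpec.paced(1.0),
                         duration_s=TEST_DURATION_S)
        traj = simulate(baseline_cell, cond, solver=solver)
        rec = extract_window(traj, cond)
        ups = detect_upstrokes(rec.t_ms, rec.vm)
        assert ups.size == 5  # 5 s window at 1 Hz
        periods = np.diff(rec.t_ms[ups])
        assert np.allclose(periods, 1000.0, atol=25.0)

    def test_gkr_increase_does_not_lengthen_apd(self, baseline_cell,
                                                baseline_recording, solver,
                                                physio_condition):
        faster = baseline_cell.replace(G_Kr=1.5)
        rec = extract_window(simulate(faster, physio_condition,
                                      solver=solver), physio_condition)
        apd_base = extract_features(baseline_recording).apd90_ms
        apd_fast = extract_features(rec).apd90_ms
        assert apd_fast <= apd_base

    def test_timeout_raises(self, baseline_cell):
        cond = Condition("physio", duration_s=60.0)
        solver = SolverSettings(time_limit_s=1e-4)
        with pytest.raises(SimulationTimeout):
            simulate(baseline_cell, cond, solver=solver)

    def test_gating_invariants_along_trajectory(self, baseline_trajectory):
        baseline_trajectory.check_invariants(tol=1e-3)

    def test_export_round_trip(self, baseline_trajectory, tmp_path):
        csv = tmp_path / "traj.csv"
        baseline_trajectory.to_csv(csv)
        import pandas as pd

        df = pd.read_csv(csv)
        assert list(df.columns) == ["time_ms", "Vm_mV", "Cai_mM"]
        assert np.allclose(df["Vm_mV"], baseline_trajectory.vm)

        h5 = tmp_path / "traj.h5"
        baseline_trajectory.to_hdf5(h5)
        import h5py

        with h5py.File(h5) as fh:
            assert np.array_equal(fh["trajectory/Vm_mV"][...],
                                  baseline_trajectory.vm)


class TestTrajectory:
    def test_interp_exact_at_samples(self):
        t = np.arange(0, 10.0, 0.5)
        states = np.random.default_rng(0).normal(size=(t.size, 20))
        traj = Trajectory(t, states)
        assert np.allclose(traj.interp(t), states)

    def test_rejects_nonmonotone_time(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros((3, 20)))
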