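"""Windowing, normalization, protocol chaining and the condition catalog."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipsctwin.model_core import StimulusSpec, Trajectory, simulate
from ipsctwin.protocols import (
    Condition,
    DegenerateSignalError,
    Protocol,
    Recording,
    default_catalog,
    extract_window,
    load_catalog,
    named_protocols,
    normalize,
    run_protocol,
    save_catalog,
    validation_conditions,
)
from ipsctwin.evaluation import detect_upstrokes

from conftest import TEST_DURATION_S


def _synthetic_trajectory(duration_ms=6000.0, dt=0.1):
    t = np.arange(0.0, duration_ms + dt / 2, dt)
    states = np.zeros((t.size, 20))
    states[:, 0] = np.sin(2 * np.pi * t / 1000.0) * 50.0 - 30.0
    states[:, 1] = 1e-4 + 5e-5 * np.cos(2 * np.pi * t / 1000.0)
    return Trajectory(t, states)


class TestExtractWindow:
    def test_grid_arithmetic_5s_window(self):
        rec = extract_window(_synthetic_trajectory())
        assert rec.n_samples == 50001
        assert rec.dt_ms == pytest.approx(0.1)
        assert rec.window_s == pytest.approx(5.0)

    def test_values_preserved_on_matching_grid(self):
        traj = _synthetic_trajectory()
        rec = extract_window(traj)
        sel = traj.t_ms >= traj.t_ms[-1] - 5000.0
        assert np.allclose(rec.vm, traj.vm[sel], atol=1e-12)

    def test_linear_ramp_interpolated_exactly(self):
        t = np.arange(0.0, 6000.0, 0.37)  # off-grid sampling
        states = np.zeros((t.size, 20))
        states[:, 0] = t  # Vm(t) = t
        rec = extract_window(Trajectory(t, states))
        expected = rec.t_ms + (t[-1] - 5000.0)
        assert np.allclose(rec.vm, expected, atol=1e-9)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            extract_window(_synthetic_trajectory(duration_ms=1000.0))


class TestNormalize:
    def test_endpoints_map_to_unit_interval(self):
        rec = extract_window(_synthetic_trajectory())
        out = normalize(rec)
        assert out.vm.min() == pytest.approx(0.0)
        assert out.vm.max() == pytest.approx(1.0)
        assert out.cai.min() == pytest.approx(0.0)
        assert out.cai.max() == pytest.approx(1.0)
        assert out.normalized

    def test_idempotent(self):
        rec = normalize(extract_window(_synthetic_trajectory()))
        again = normalize(rec)
        assert np.allclose(again.vm, rec.vm)
        assert np.allclose(again.cai, rec.cai)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, a, b):
        """normalize(a*Vm + b) == normalize(Vm) for a > 0 -- the premise that
        lets min-max normalized fluorescence stand in for calibrated data."""
        rec = extract_window(_synthetic_trajectory(duration_ms=5200.0))
        scaled = Recording(rec.condition_label, rec.t_ms, a * rec.vm + b,
                           a * rec.cai + b)
        assert np.allclose(normalize(scaled).vm, normalize(rec).vm,
                           atol=1e-9)

    def test_constant_channel_raises_degenerate(self):
        t = np.arange(0.0, 5000.1, 0.1)
        rec = Recording("flat", t, np.full_like(t, -70.0),
                        np.full_like(t, 1e-4))
        with pytest.raises(DegenerateSignalError, match="constant"):
            normalize(rec)


class TestRunProtocol:
    def test_single_condition_equals_simulate_plus_window(
            self, baseline_cell, solver):
        cond = Condition("physio", duration_s=10.0)
        proto = Protocol("single", (cond,))
        [rec] = run_protocol(baseline_cell, proto, solver=solver)
        direct = extract_window(simulate(baseline_cell, cond, solver=solver),
                                cond)
        assert np.array_equal(rec.vm, direct.vm)
        assert np.array_equal(rec.cai, direct.cai)

    def test_carry_over_reaches_quasi_steady_second_condition(
            self, baseline_cell, solver):
        """Chaining two identical physiological conditions: the second
        window starts from the first's final state, so beat rates agree."""
        cond = Condition("physio", duration_s=TEST_DURATION_S)
        proto = Protocol("twice", (cond, cond), carry_over=True)
        rec1, rec2 = run_protocol(baseline_cell, proto, solver=solver)
        r1 = detect_upstrokes(rec1.t_ms, rec1.vm).size
        r2 = detect_upstrokes(rec2.t_ms, rec2.vm).size
        assert abs(r1 - r2) <= 1

    def test_order_invariance_without_carry_over(self, baseline_cell, solver):
        c1 = Condition("a", duration_s=8.0, cao_mM=1.0)
        c2 = Condition("b", duration_s=8.0, cao_mM=2.7)
        fwd = run_protocol(baseline_cell, Protocol("fwd", (c1, c2),
                                                   carry_over=False),
                           solver=solver)
        rev = run_protocol(baseline_cell, Protocol("rev", (c2, c1),
                                                   carry_over=False),
                           solver=solver)
        assert np.array_equal(fwd[0].vm, rev[1].vm)
        assert np.array_equal(fwd[1].vm, rev[0].vm)

    def test_paced_beat_counts_across_ca_switch(self, baseline_cell, solver):
        """1.8 then 1.0 mM Ca2+ at 1 Hz pacing: both recordings show the
        pacing rate (5 beats in the 5 s window)."""
        c1 = Condition("ca1.8", pacing=StimulusSpec.paced(1.0),
                       duration_s=TEST_DURATION_S)
        c2 = Condition("ca1.0", pacing=StimulusSpec.paced(1.0), cao_mM=1.0,
                       duration_s=TEST_DURATION_S)
        recs = run_protocol(baseline_cell, Protocol("p", (c1, c2)),
                            solver=solver)
        for rec in recs:
            assert detect_upstrokes(rec.t_ms, rec.vm).size == 5


class TestCatalog:
    def test_nineteen_conditions_no_ikr_block(self):
        cat = default_catalog()
        assert len(cat) == 19
        assert len({c.label for c in cat}) == 19
        for c in cat:
            assert "I_Kr" not in c.blocks
        assert all(c.duration_s == 300.0 for c in cat)

    def test_validation_conditions_include_ikr30_and_hypo_2hz(self):
        vals = validation_conditions()
        blocks = [c.blocks.get("I_Kr", 0) for c in vals]
        assert 0.30 in blocks
        labels = {c.label for c in vals}
        assert "ca1.0-2hz" in labels

    def test_named_protocols_resolve_catalog_entries(self):
        protos = named_protocols()
        assert protos["optimized-3"].labels == (
            "ca1.0-1hz", "ca1.8-1hz", "ca1.8-1.25hz")
        assert len(protos["single-spont"].conditions) == 1

    def test_catalog_yaml_round_trip(self, tmp_path):
        cat = default_catalog(30.0)
        path = tmp_path / "catalog.yaml"
        save_catalog(cat, path)
        back = load_catalog(path)
        assert [c.label for c in back] == [c.label for c in cat]
        assert all(a == b for a, b in zip(back, cat))
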