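"""Shared fixtures.

Simulation-backed fixtures are session-scoped and run at reduced
pre-equilibration durations (tens of seconds instead of the standard
300 s) to keep the suite fast; the full-duration behavior is exercised in
the acceptance tests.
"""

import numpy as np
import pytest

from ipsctwin.model_core import ConductanceSet, SolverSettings, simulate
from ipsctwin.population import (
    PopulationSpec,
    filter_spontaneous,
    physiological_condition,
    sample_population,
)
from ipsctwin.protocols import Recording, extract_window, normalize

#: reduced per-condition duration for unit tests (s)
TEST_DURATION_S = 20.0


@pytest.fixture(scope="session")
def baseline_cell():
    return ConductanceSet.baseline()


@pytest.fixture(scope="session")
def solver():
    return SolverSettings()


@pytest.fixture(scope="session")
def physio_condition():
    return physiological_condition(TEST_DURATION_S)


@pytest.fixture(scope="session")
def baseline_trajectory(baseline_cell, physio_condition, solver):
    return simulate(baseline_cell, physio_condition, solver=solver)


@pytest.fixture(scope="session")
def baseline_recording(baseline_trajectory, physio_condition):
    return extract_window(baseline_trajectory, physio_condition)


@pytest.fixture(scope="session")
def baseline_recording_normalized(baseline_recording):
    return normalize(baseline_recording)


@pytest.fixture(scope="session")
def fixture_cells(solver):
    """Two heterogeneous cells from the frozen-seed population that pass the
    spontaneous-rate filter at test scale."""
    cells = sample_population(PopulationSpec(n=10, sigma=0.2, seed=7))
    cond = physiological_condition(TEST_DURATION_S)
    kept, rates, _ = filter_spontaneous(cells, (0.3, 1.0), condition=cond,
                                        solver=solver)
    assert len(kept) >= 2, "fixture population must yield >= 2 beating cells"
    return kept[:2]


def triangle_recording(n_beats=4, period_ms=1000.0, rise_ms=10.0,
                       fall_ms=300.0, peak=20.0, base=-80.0, dt_ms=0.1,
                       fall_ms_alt=None, pacing=None,
                       normalized=False) -> Recording:
    """Synthetic triangular-AP voltage trace with a matching Ca channel.

    Each beat rises linearly base->peak over ``rise_ms`` and falls linearly
    back over ``fall_ms`` (alternating with ``fall_ms_alt`` when given);
    diastole is flat at ``base``.
    """
    total_ms = n_beats * period_ms
    t = np.arange(0.0, total_ms + dt_ms / 2, dt_ms)
    v = np.full_like(t, base)
    ca = np.zeros_like(t)
    for b in range(n_beats):
        fall = fall_ms if (fall_ms_alt is None or b % 2 == 0) else fall_ms_alt
        t0 = b * period_ms + 50.0
        rise_mask = (t >= t0) & (t < t0 + rise_ms)
        v[rise_mask] = base + (peak - base) * (t[rise_mask] - t0) / rise_ms
        fall_mask = (t >= t0 + rise_ms) & (t < t0 + rise_ms + fall)
        v[fall_mask] = peak - (peak - base) * (
            t[fall_mask] - t0 - rise_ms) / fall
        ca_mask = (t >= t0) & (t < t0 + rise_ms + fall)
        ca[ca_mask] = np.sin(
            np.pi * (t[ca_mask] - t0) / (rise_ms + fall)) ** 2
    return Recording("triangle", t, v, ca, normalized=normalized,
                     pacing=pacing)
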