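"""Deterministic simulator of the iPSC-CM electrophysiology ODE model.

The model couples membrane potential, intracellular/SR Ca2+ handling and
dynamic Na+/K+ concentrations, parameterized by 16 maximal-conductance scale
factors (:data:`~ipsctwin.constants.CONDUCTANCE_NAMES`).  A multiplier of 1.0
on every parameter reproduces the baseline cell, which beats spontaneously in
the 0.3-1.0 Hz automaticity range of human iPSC-CMs and follows 1-2 Hz field
pacing (60 pA/pF, 1 ms square pulses).

The kinetic parameterization is a documented synthetic stand-in (see
``data/model_constants.yaml`` and docs/methods.md): current structure and
conductance interface follow the iPSC-CM digital-twin literature, kinetics
are assembled from standard human-myocyte formulations.

Integration strategy: stiff multistep integration (LSODA, automatic BDF
fallback) over segments split at every stimulus-pulse edge, so the
right-hand side is continuous within each solver call.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.integrate import odeint, solve_ivp

from . import _kernel as kernel
from .constants import (
    BASELINE_VECTOR,
    CONDUCTANCE_NAMES,
    CURRENT_NAMES,
    CURRENT_TO_CONDUCTANCE,
    DEFAULT_KO,
    DEFAULT_NAO,
    DEFAULT_STIM_AMPLITUDE,
    DEFAULT_STIM_DURATION_MS,
    REFERENCE_INITIAL_STATE,
    STATE_NAMES,
)

__all__ = [
    "ConductanceSet", "StimulusSpec", "SolverSettings", "Trajectory",
    "ModelError", "UnknownCurrentError", "BlockRangeError",
    "IntegrationError", "SimulationTimeout",
    "derivatives", "currents", "simulate", "apply_block",
]


class ModelError(Exception):
    """Base class for simulator errors."""


class UnknownCurrentError(ModelError):
    """A block map referred to a current the model does not have."""


class BlockRangeError(ModelError):
    """A block fraction fell outside [0, 1]."""


class IntegrationError(ModelError):
    """Step-size collapse; carries the last time (ms) reached successfully."""

    def __init__(self, message: str, last_valid_time_ms: float):
        super().__init__(message)
        self.last_valid_time_ms = last_valid_time_ms


class SimulationTimeout(ModelError):
    """The hard wall-clock limit of :class:`SolverSettings` was exceeded."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductanceSet:
    """The 16 maximal-conductance scale factors defining one model cell.

    ``multipliers`` maps each canonical parameter name to a positive,
    dimensionless factor; 1.0 everywhere is the published-baseline cell.
    """

    multipliers: dict[str, float]

    def __post_init__(self):
        if set(self.multipliers) != set(CONDUCTANCE_NAMES):
            missing = set(CONDUCTANCE_NAMES) - set(self.multipliers)
            extra = set(self.multipliers) - set(CONDUCTANCE_NAMES)
            raise ValueError(
                f"conductance set must have exactly the 16 canonical entries; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, value in self.multipliers.items():
            if not (value > 0):
                raise ValueError(f"multiplier {name}={value!r} must be > 0")

    @classmethod
    def baseline(cls) -> "ConductanceSet":
        return cls({name: 1.0 for name in CONDUCTANCE_NAMES})

    @classmethod
    def from_vector(cls, vec) -> "ConductanceSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (16,):
            raise ValueError("expected 16 multipliers")
        return cls(dict(zip(CONDUCTANCE_NAMES, vec.tolist())))

    def to_vector(self) -> np.ndarray:
        return np.array([self.multipliers[n] for n in CONDUCTANCE_NAMES])

    def __getitem__(self, name: str) -> float:
        return self.multipliers[name]

    def replace(self, **updates: float) -> "ConductanceSet":
        unknown = set(updates) - set(CONDUCTANCE_NAMES)
        if unknown:
            raise KeyError(f"unknown conductance parameters: {sorted(unknown)}")
        merged = dict(self.multipliers)
        merged.update(updates)
        return ConductanceSet(merged)


@dataclass(frozen=True)
class StimulusSpec:
    """Square-pulse pacing: amplitude in pA/pF, pulse duration and period in
    ms.  ``period_ms=None`` means spontaneous (no stimulation).  The first
    pulse starts at t = 0 of the paced segment."""

    amplitude: float = DEFAULT_STIM_AMPLITUDE
    duration_ms: float = DEFAULT_STIM_DURATION_MS
    period_ms: float | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if self.amplitude > 0 and not (self.duration_ms > 0):
            raise ValueError("pulse duration must be > 0 when amplitude > 0")
        if self.period_ms is not None and not (self.period_ms > 0):
            raise ValueError("period must be > 0 or None")

    @classmethod
    def paced(cls, frequency_hz: float,
              amplitude: float = DEFAULT_STIM_AMPLITUDE,
              duration_ms: float = DEFAULT_STIM_DURATION_MS) -> "StimulusSpec":
        if not (frequency_hz > 0):
            raise ValueError("pacing frequency must be > 0")
        return cls(amplitude=amplitude, duration_ms=duration_ms,
                   period_ms=1000.0 / frequency_hz)

    @classmethod
    def spontaneous(cls) -> "StimulusSpec":
        return cls(amplitude=0.0, period_ms=None)

    @property
    def is_paced(self) -> bool:
        return self.period_ms is not None and self.amplitude > 0

    @property
    def frequency_hz(self) -> float | None:
        return None if self.period_ms is None else 1000.0 / self.period_ms


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator configuration.

    ``rtol``/``atol`` are the LSODA tolerances (``atol`` is scaled per state
    class internally: looser on Vm/Nai/Ki, tighter on Cai).  ``time_limit_s``
    is a hard wall-clock budget; exceeding it raises
    :class:`SimulationTimeout` (the GA maps that to worst fitness).
    ``output_dt_ms`` is the coarse recording step; the final
    ``fine_window_s`` of a run is recorded at ``fine_dt_ms``.
    """

    rtol: float = 1e-6
    atol: float = 1e-8
    max_step_ms: float = 0.0  # 0 = unrestricted
    method: str = "lsoda"
    time_limit_s: float = float("inf")
    output_dt_ms: float = 1.0
    fine_dt_ms: float = 0.1
    fine_window_s: float = 6.0
    chunk_ms: float = 2000.0

    def __post_init__(self):
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be > 0")
        if self.method not in ("lsoda", "bdf"):
            raise ValueError("method must be 'lsoda' or 'bdf'")

    def atol_vector(self) -> np.ndarray:
        atol = np.full(kernel.N_STATES, self.atol)
        scale = self.atol / 1e-8  # keep user intent when tightening/loosening
        atol[kernel.IV] = 1e-6 * scale
        atol[kernel.INAI] = 1e-6 * scale
        atol[kernel.IKI] = 1e-6 * scale
        atol[kernel.ICAI] = 1e-10 * scale
        return atol


class Trajectory:
    """Dense model output: time (ms) and the full state matrix.

    Values on arbitrary grids are obtained by linear interpolation, which is
    exact at the stored sample points.
    """

    def __init__(self, t_ms: np.ndarray, states: np.ndarray):
        t_ms = np.asarray(t_ms, dtype=float)
        states = np.asarray(states, dtype=float)
        if states.shape != (t_ms.size, kernel.N_STATES):
            raise ValueError("states must be (n_times, n_states)")
        if np.any(np.diff(t_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")
        self.t_ms = t_ms
        self.states = states

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    @property
    def vm(self) -> np.ndarray:
        return self.states[:, kernel.IV]

    @property
    def cai(self) -> np.ndarray:
        return self.states[:, kernel.ICAI]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def interp(self, t_ms: np.ndarray) -> np.ndarray:
        t_ms = np.asarray(t_ms, dtype=float)
        out = np.empty((t_ms.size, self.states.shape[1]))
        for k in range(self.states.shape[1]):
            out[:, k] = np.interp(t_ms, self.t_ms, self.states[:, k])
        return out

    def check_invariants(self, tol: float = 1e-6) -> None:
        """Post-hoc physical sanity: gates in [0,1], concentrations >= 0."""
        gates = self.states[:, 5:]
        if gates.min() < -tol or gates.max() > 1 + tol:
            raise AssertionError("gating variable escaped [0, 1]")
        conc = self.states[:, 1:5]
        if conc.min() < -tol:
            raise AssertionError("negative ion concentration")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.t_ms,
            "Vm_mV": self.vm,
            "Cai_mM": self.cai,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path, dataset: str = "trajectory") -> None:
        with h5py.File(path, "a") as fh:
            grp = fh.require_group(dataset)
            for key in ("time_ms", "Vm_mV", "Cai_mM"):
                if key in grp:
                    del grp[key]
            grp.create_dataset("time_ms", data=self.t_ms, track_times=False)
            grp.create_dataset("Vm_mV", data=self.vm, track_times=False)
            grp.create_dataset("Cai_mM", data=self.cai, track_times=False)


# ---------------------------------------------------------------------------
# parameter assembly
# ---------------------------------------------------------------------------

def _validate_blocks(blocks: dict[str, float]) -> None:
    for name, frac in blocks.items():
        if name not in CURRENT_TO_CONDUCTANCE:
            raise UnknownCurrentError(
                f"cannot block unknown current {name!r}; known: "
                f"{sorted(CURRENT_TO_CONDUCTANCE)}"
            )
        if not (0.0 <= frac <= 1.0):
            raise BlockRangeError(f"block fraction for {name} must be in [0, 1], got {frac}")


def apply_block(cs: ConductanceSet, blocks: dict[str, float]) -> ConductanceSet:
    """Return a new set with each blocked current's multiplier scaled by
    (1 - fraction); the input is untouched."""
    _validate_blocks(blocks)
    updated = dict(cs.multipliers)
    for current, frac in blocks.items():
        gname = CURRENT_TO_CONDUCTANCE[current]
        updated[gname] = updated[gname] * (1.0 - frac)
    if any(v <= 0 for v in updated.values()):
        # full block: represent "zero conductance" by the smallest positive
        # float so the ConductanceSet positivity invariant is kept
        updated = {k: (v if v > 0 else 5e-324) for k, v in updated.items()}
    return ConductanceSet(updated)


def _param_vector(cs: ConductanceSet, cond, stim: StimulusSpec | None) -> np.ndarray:
    """Pack effective conductances + milieu + stimulus into the kernel layout."""
    blocks = getattr(cond, "blocks", {}) or {}
    _validate_blocks(blocks)
    eff = BASELINE_VECTOR * cs.to_vector()
    for current, frac in blocks.items():
        idx = CONDUCTANCE_NAMES.index(CURRENT_TO_CONDUCTANCE[current])
        eff[idx] *= (1.0 - frac)
    p = np.zeros(kernel.N_PARAMS)
    p[:16] = eff
    p[kernel.IP_CAO] = getattr(cond, "cao_mM", None) or getattr(cond, "cao", 1.8)
    p[kernel.IP_NAO] = getattr(cond, "nao_mM", DEFAULT_NAO)
    p[kernel.IP_KO] = getattr(cond, "ko_mM", DEFAULT_KO)
    if stim is None:
        stim = getattr(cond, "pacing", None) or StimulusSpec.spontaneous()
    if stim.is_paced:
        p[kernel.IP_AMP] = stim.amplitude
        p[kernel.IP_DUR] = stim.duration_ms
        p[kernel.IP_PER] = stim.period_ms
    return p


def derivatives(state, t_ms: float, cs: ConductanceSet, cond,
                stim: StimulusSpec | None = None) -> np.ndarray:
    """Time derivative of every state entry at time ``t_ms``.

    The stimulus term is included whenever ``t_ms`` falls inside a pulse of
    the pacing spec.
    """
    p = _param_vector(cs, cond, stim)
    if p[kernel.IP_PER] > 0 and (t_ms % p[kernel.IP_PER]) < p[kernel.IP_DUR]:
        p[kernel.IP_ON] = 1.0
    return kernel.rhs(float(t_ms), np.asarray(state, dtype=float), p)


def currents(state, t_ms: float, cs: ConductanceSet, cond,
             stim: StimulusSpec | None = None) -> dict[str, float]:
    """Individual membrane current densities (pA/pF) and SR fluxes (mM/ms)."""
    p = _param_vector(cs, cond, stim)
    if p[kernel.IP_PER] > 0 and (t_ms % p[kernel.IP_PER]) < p[kernel.IP_DUR]:
        p[kernel.IP_ON] = 1.0
    buf = np.empty(kernel.N_CURRENTS)
    kernel.compute(float(t_ms), np.asarray(state, dtype=float), p, buf)
    return dict(zip(CURRENT_NAMES, buf.tolist()))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _segment_edges(duration_ms: float, stim: StimulusSpec,
                   chunk_ms: float) -> np.ndarray:
    edges = [0.0, duration_ms]
    if stim.is_paced:
        k = 0
        per, dur = stim.period_ms, stim.duration_ms
        while k * per < duration_ms:
            edges.append(k * per)
            edges.append(min(k * per + dur, duration_ms))
            k += 1
    edges = np.unique(np.asarray(edges))
    # bound solver-call length (very long LSODA calls are fragile)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        out.append(a)
        n = int((b - a) // chunk_ms)
        out.extend(a + chunk_ms * i for i in range(1, n + 1)
                   if a + chunk_ms * i < b - 1e-9)
    out.append(edges[-1])
    return np.asarray(out)


def _integrate_segment(y, tseg, p, solver: SolverSettings, atol_vec):
    if solver.method == "lsoda":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # failures handled via `info`
            sol, info = odeint(
                kernel.rhs_odeint, y, tseg, args=(p,), rtol=solver.rtol,
                atol=atol_vec, hmax=solver.max_step_ms, mxstep=20000,
                full_output=True, printmessg=False,
            )
        if info["message"] == "Integration successful." and np.all(np.isfinite(sol)):
            return sol
    res = solve_ivp(
        kernel.rhs, (tseg[0], tseg[-1]), y, method="BDF", t_eval=tseg,
        args=(p,), rtol=solver.rtol, atol=atol_vec,
        max_step=solver.max_step_ms or np.inf,
    )
    if not res.success or not np.all(np.isfinite(res.y)):
        raise IntegrationError(
            f"stiff integration failed near t={tseg[0]:.3f} ms: {res.message}",
            last_valid_time_ms=float(tseg[0]),
        )
    return res.y.T


def simulate(cs: ConductanceSet, cond, duration_s: float | None = None,
             init: np.ndarray | None = None,
             solver: SolverSettings | None = None) -> Trajectory:
    """Run the model under one experimental condition.

    Deterministic given its inputs.  ``duration_s`` defaults to the
    condition's duration (300 s in the standard protocol); ``init`` defaults
    to the package reference initial state.  Output is recorded at
    ``solver.output_dt_ms`` except for the final ``solver.fine_window_s``,
    recorded at ``solver.fine_dt_ms`` for downstream windowing.
    """
    solver = solver or SolverSettings()
    if duration_s is None:
        duration_s = getattr(cond, "duration_s", 300.0)
    if not (duration_s > 0):
        raise ValueError("duration must be > 0")
    duration_ms = float(duration_s) * 1000.0
    y = np.array(REFERENCE_INITIAL_STATE if init is None else init, dtype=float)
    if y.shape != (kernel.N_STATES,):
        raise ValueError(f"initial state must have {kernel.N_STATES} entries")

    stim = getattr(cond, "pacing", None) or StimulusSpec.spontaneous()
    p = _param_vector(cs, cond, stim)
    atol_vec = solver.atol_vector()

    fine_start = max(0.0, duration_ms - solver.fine_window_s * 1000.0)
    coarse = np.arange(0.0, fine_start, solver.output_dt_ms)
    fine = np.arange(fine_start, duration_ms, solver.fine_dt_ms)
    grid = np.unique(np.concatenate((coarse, fine, [duration_ms])))

    edges = _segment_edges(duration_ms, stim, solver.chunk_ms)
    t_out = [np.array([0.0])]
    y_out = [y[None, :]]
    deadline = _time.monotonic() + solver.time_limit_s
    for a, b in zip(edges[:-1], edges[1:]):
        if _time.monotonic() > deadline:
            raise SimulationTimeout(
                f"wall-clock limit {solver.time_limit_s} s exceeded at "
                f"t={a:.0f} ms of {duration_ms:.0f} ms"
            )
        pseg = p.copy()
        if stim.is_paced and (((a + b) / 2.0) % stim.period_ms) < stim.duration_ms:
            pseg[kernel.IP_ON] = 1.0
        inner = grid[(grid > a + 1e-9) & (grid < b - 1e-9)]
        tseg = np.concatenate(([a], inner, [b]))
        sol = _integrate_segment(y, tseg, pseg, solver, atol_vec)
        y = sol[-1]
        t_out.append(tseg[1:])
        y_out.append(sol[1:])
    return Trajectory(np.concatenate(t_out), np.concatenate(y_out))
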