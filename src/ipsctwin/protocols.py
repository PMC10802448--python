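"""Experimental conditions, chained protocols and windowed recordings.

A :class:`Condition` is one experimental context (pacing, buffer Ca2+,
channel blocks, duration); a :class:`Protocol` is an ordered chain of
conditions.  When a protocol is run, the final model state of condition *k*
seeds condition *k+1* (state carry-over), mirroring how a dish moves through
solution changes in the recording rig.  Each condition contributes one
:class:`Recording`: the final 5 s of its simulation, interpolated onto a
uniform 0.1 ms grid, optionally min-max normalized per channel to emulate
fluorescence data.

The default 19-condition catalog is built from three experimentally cheap
axes -- buffer Ca2+ (hypo 1.0 / normal 1.8 / hyper 2.7 mM), pacing
(spontaneous, 1, 1.25, 1.5, 2 Hz) and partial L-type Ca2+ channel block
(0/25/50 %).  IKr-block conditions are excluded from calibration catalogs
and reserved for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import yaml

from .model_core import (
    ModelError,
    ConductanceSet,
    SolverSettings,
    StimulusSpec,
    Trajectory,
    simulate,
)

__all__ = [
    "Condition", "Protocol", "Recording",
    "DegenerateSignalError", "ProtocolSimulationError",
    "extract_window", "normalize", "run_protocol",
    "default_catalog", "validation_conditions", "named_protocols",
    "save_catalog", "load_catalog",
]

WINDOW_S = 5.0
DT_MS = 0.1


class DegenerateSignalError(ModelError):
    """A channel was constant, so min-max normalization is undefined
    (dead/quiescent trace)."""


class ProtocolSimulationError(ModelError):
    """Simulation failed inside a protocol; carries the condition label."""

    def __init__(self, label: str, cause: Exception):
        super().__init__(f"condition {label!r}: {cause}")
        self.condition_label = label
        self.__cause__ = cause


@dataclass(frozen=True)
class Condition:
    """One experimental context.

    ``pacing=None`` means spontaneous beating.  ``blocks`` maps current
    names (e.g. ``"I_Kr"``) to fractional block in [0, 1].
    """

    label: str
    pacing: StimulusSpec | None = None
    cao_mM: float = 1.8
    blocks: dict[str, float] = field(default_factory=dict)
    duration_s: float = 300.0

    def __post_init__(self):
        if not (self.cao_mM > 0):
            raise ValueError("extracellular Ca2+ must be > 0")
        if not (self.duration_s > 0):
            raise ValueError("duration must be > 0")

    @property
    def is_paced(self) -> bool:
        return self.pacing is not None and self.pacing.is_paced

    def with_duration(self, duration_s: float) -> "Condition":
        return replace(self, duration_s=duration_s)

    def with_blocks(self, blocks: dict[str, float]) -> "Condition":
        merged = dict(self.blocks)
        merged.update(blocks)
        return replace(self, blocks=merged)

    def to_dict(self) -> dict:
        d = {"label": self.label, "cao_mM": self.cao_mM,
             "duration_s": self.duration_s, "blocks": dict(self.blocks)}
        if self.pacing is not None and self.pacing.is_paced:
            d["pacing_hz"] = self.pacing.frequency_hz
            d["stim_amplitude"] = self.pacing.amplitude
            d["stim_duration_ms"] = self.pacing.duration_ms
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        pacing = None
        if d.get("pacing_hz"):
            pacing = StimulusSpec.paced(
                d["pacing_hz"],
                amplitude=d.get("stim_amplitude", 60.0),
                duration_ms=d.get("stim_duration_ms", 1.0),
            )
        return cls(label=d["label"], pacing=pacing, cao_mM=d.get("cao_mM", 1.8),
                   blocks=dict(d.get("blocks", {})),
                   duration_s=d.get("duration_s", 300.0))


@dataclass(frozen=True)
class Protocol:
    """Ordered chain of conditions; with ``carry_over`` (default) each
    condition starts from the previous condition's final state."""

    name: str
    conditions: tuple[Condition, ...]
    carry_over: bool = True

    def __post_init__(self):
        if len(self.conditions) == 0:
            raise ValueError("protocol must contain at least one condition")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def with_duration(self, duration_s: float) -> "Protocol":
        return replace(self, conditions=tuple(
            c.with_duration(duration_s) for c in self.conditions))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)


class Recording:
    """Uniformly sampled (t, Vm, Cai) window for one condition.

    The grid step is exactly 0.1 ms over a 5 s window (50,001 samples);
    time is relative to the window start.  A normalized recording has each
    channel min-max scaled to [0, 1].
    """

    def __init__(self, condition_label: str, t_ms: np.ndarray, vm: np.ndarray,
                 cai: np.ndarray, normalized: bool = False,
                 pacing: StimulusSpec | None = None):
        t_ms = np.asarray(t_ms, dtype=float)
        vm = np.asarray(vm, dtype=float)
        cai = np.asarray(cai, dtype=float)
        if not (t_ms.shape == vm.shape == cai.shape):
            raise ValueError("t, Vm, Cai must have identical shape")
        steps = np.diff(t_ms)
        if t_ms.size < 2 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("recording grid must be uniform")
        self.condition_label = condition_label
        self.t_ms = t_ms
        self.vm = vm
        self.cai = cai
        self.normalized = bool(normalized)
        self.pacing = pacing

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def window_s(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0]) / 1000.0

    @property
    def n_samples(self) -> int:
        return self.t_ms.size

    def channel(self, name: str) -> np.ndarray:
        if name in ("v", "V", "vm"):
            return self.vm
        if name in ("ca", "Ca", "cai"):
            return self.cai
        raise KeyError(f"unknown channel {name!r}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.t_ms, "vm": self.vm, "cai": self.cai})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition_label: str = "",
                 normalized: bool = False) -> "Recording":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(condition_label, df["time_ms"].to_numpy(),
                   df["vm"].to_numpy(), df["cai"].to_numpy(),
                   normalized=normalized)

    def to_hdf5_group(self, grp: h5py.Group) -> None:
        for key, data in (("time_ms", self.t_ms), ("vm", self.vm),
                          ("cai", self.cai)):
            if key in grp:
                del grp[key]
            grp.create_dataset(key, data=data, track_times=False)
        grp.attrs["condition_label"] = self.condition_label
        grp.attrs["normalized"] = self.normalized
        grp.attrs["pacing_hz"] = (self.pacing.frequency_hz
                                  if self.pacing and self.pacing.is_paced
                                  else 0.0)

    @classmethod
    def from_hdf5_group(cls, grp: h5py.Group) -> "Recording":
        hz = float(grp.attrs.get("pacing_hz", 0.0))
        pacing = StimulusSpec.paced(hz) if hz > 0 else None
        return cls(
            str(grp.attrs["condition_label"]),
            grp["time_ms"][...], grp["vm"][...], grp["cai"][...],
            normalized=bool(grp.attrs["normalized"]), pacing=pacing,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_window(trajectory: Trajectory, condition: Condition | None = None,
                   window_s: float = WINDOW_S,
                   dt_ms: float = DT_MS) -> Recording:
    """Final ``window_s`` of a trajectory, linearly interpolated onto the
    uniform ``dt_ms`` grid ending at the trajectory's last time point."""
    window_ms = window_s * 1000.0
    if trajectory.duration_ms + 1e-9 < window_ms:
        raise ValueError(
            f"trajectory ({trajectory.duration_ms:.1f} ms) shorter than "
            f"requested window ({window_ms:.1f} ms)")
    t_end = trajectory.t_ms[-1]
    n = int(round(window_ms / dt_ms))
    grid = t_end - window_ms + np.arange(n + 1) * dt_ms
    vm = np.interp(grid, trajectory.t_ms, trajectory.vm)
    cai = np.interp(grid, trajectory.t_ms, trajectory.cai)
    label = condition.label if condition is not None else ""
    pacing = condition.pacing if condition is not None else None
    return Recording(label, grid - grid[0], vm, cai, normalized=False,
                     pacing=pacing)


def normalize(rec: Recording) -> Recording:
    """Min-max scale each channel to [0, 1] within the recording.

    Raises :class:`DegenerateSignalError` on a constant channel, which
    signals a dead or quiescent trace to the caller (the GA maps this to
    worst fitness).  Idempotent, and invariant to affine rescaling of the
    raw channels.
    """
    channels = []
    for name, x in (("vm", rec.vm), ("cai", rec.cai)):
        lo, hi = float(np.min(x)), float(np.max(x))
        span = hi - lo
        if span <= 1e-12 * max(1.0, abs(hi), abs(lo)):
            raise DegenerateSignalError(
                f"channel {name} of condition {rec.condition_label!r} is "
                f"constant (value {hi:.6g}); cannot normalize")
        channels.append((x - lo) / span)
    return Recording(rec.condition_label, rec.t_ms.copy(), channels[0],
                     channels[1], normalized=True, pacing=rec.pacing)


def run_protocol(cs: ConductanceSet, protocol: Protocol,
                 solver: SolverSettings | None = None,
                 init: np.ndarray | None = None,
                 window_s: float = WINDOW_S,
                 dt_ms: float = DT_MS) -> list[Recording]:
    """Simulate every condition of a protocol and window each one.

    With carry-over on, condition *k+1* starts from condition *k*'s final
    state; with carry-over off, every condition starts from the package
    default initial state (or ``init``).
    """
    solver = solver or SolverSettings()
    recordings: list[Recording] = []
    state = init
    for cond in protocol.conditions:
        try:
            traj = simulate(cs, cond, init=state, solver=solver)
        except ModelError as exc:
            raise ProtocolSimulationError(cond.label, exc) from exc
        recordings.append(extract_window(traj, cond, window_s=window_s,
                                         dt_ms=dt_ms))
        state = traj.final_state if protocol.carry_over else init
    return recordings


# ---------------------------------------------------------------------------
# condition catalog
# ---------------------------------------------------------------------------

_HYPO, _NORMAL, _HYPER = 1.0, 1.8, 2.7


def _cond(label, hz=None, cao=_NORMAL, ical=0.0, duration_s=300.0):
    pacing = StimulusSpec.paced(hz) if hz else None
    blocks = {"I_CaL": ical} if ical else {}
    return Condition(label, pacing=pacing, cao_mM=cao, blocks=blocks,
                     duration_s=duration_s)


def default_catalog(duration_s: float = 300.0) -> list[Condition]:
    """The package's 19-condition calibration catalog.

    Built from the buffer-Ca2+ / pacing-rate / ICaL-block axes; IKr-block
    conditions are deliberately absent (reserved for validation).  The last
    entry is the physiological unperturbed condition.
    """
    conds = [
        # buffer Ca axis at 1 Hz
        _cond("ca1.0-1hz", hz=1.0, cao=_HYPO),
        _cond("ca1.8-1hz", hz=1.0, cao=_NORMAL),
        _cond("ca2.7-1hz", hz=1.0, cao=_HYPER),
        # pacing-rate axis at normal Ca
        _cond("ca1.8-1.25hz", hz=1.25),
        _cond("ca1.8-1.5hz", hz=1.5),
        _cond("ca1.8-2hz", hz=2.0),
        # buffer Ca axis, spontaneous
        _cond("ca1.0-spont", cao=_HYPO),
        _cond("ca2.7-spont", cao=_HYPER),
        # ICaL block at normal Ca
        _cond("ical25-1hz", hz=1.0, ical=0.25),
        _cond("ical50-1hz", hz=1.0, ical=0.50),
        _cond("ical25-spont", ical=0.25),
        _cond("ical50-spont", ical=0.50),
        # mixed Ca x rate corners
        _cond("ca1.0-1.25hz", hz=1.25, cao=_HYPO),
        _cond("ca2.7-1.25hz", hz=1.25, cao=_HYPER),
        _cond("ca1.0-2hz", hz=2.0, cao=_HYPO),
        _cond("ca2.7-2hz", hz=2.0, cao=_HYPER),
        # ICaL block x Ca corners
        _cond("ca1.0-ical25-1hz", hz=1.0, cao=_HYPO, ical=0.25),
        _cond("ca2.7-ical25-1hz", hz=1.0, cao=_HYPER, ical=0.25),
        # physiological unperturbed
        _cond("spont-physio", cao=_NORMAL),
    ]
    assert len(conds) == 19
    return [c.with_duration(duration_s) for c in conds]


def validation_conditions(duration_s: float = 300.0) -> list[Condition]:
    """Held-out conditions never used for calibration: 30 % IKr block
    (spontaneous and 1 Hz paced) and the hypo-Ca2+ 2 Hz condition."""
    return [
        Condition("ikr30-spont", cao_mM=_NORMAL, blocks={"I_Kr": 0.30},
                  duration_s=duration_s),
        Condition("ikr30-1hz", pacing=StimulusSpec.paced(1.0), cao_mM=_NORMAL,
                  blocks={"I_Kr": 0.30}, duration_s=duration_s),
        _cond("ca1.0-2hz", hz=2.0, cao=_HYPO, duration_s=duration_s),
    ]


def named_protocols(duration_s: float = 300.0) -> dict[str, Protocol]:
    """Candidate calibration protocols referenced throughout the package.

    ``optimized-3`` mirrors the in-vitro study (hypo-Ca 1 Hz, normal-Ca
    1 Hz, normal-Ca 1.25 Hz); ``mixed-3`` is the in-silico variant with an
    ICaL-block leg.  Single-condition protocols support the
    protocol-richness comparisons.
    """
    cat = {c.label: c for c in default_catalog(duration_s)}
    return {
        "optimized-3": Protocol("optimized-3", (
            cat["ca1.0-1hz"], cat["ca1.8-1hz"], cat["ca1.8-1.25hz"])),
        "mixed-3": Protocol("mixed-3", (
            cat["ca1.0-1hz"], cat["ical25-1hz"], cat["ca1.8-1.25hz"])),
        "ca-axis-3": Protocol("ca-axis-3", (
            cat["ca1.0-1hz"], cat["ca1.8-1hz"], cat["ca2.7-1hz"])),
        "rate-axis-3": Protocol("rate-axis-3", (
            cat["ca1.8-1hz"], cat["ca1.8-1.25hz"], cat["ca1.8-2hz"])),
        "ical-axis-3": Protocol("ical-axis-3", (
            cat["ca1.8-1hz"], cat["ical25-1hz"], cat["ical50-1hz"])),
        "single-spont": Protocol("single-spont", (cat["spont-physio"],)),
        "single-1hz": Protocol("single-1hz", (cat["ca1.8-1hz"],)),
        "optimized-1": Protocol("optimized-1", (cat["ca1.8-1.25hz"],)),
        "optimized-2": Protocol("optimized-2", (
            cat["ca1.8-1hz"], cat["ca1.8-1.25hz"])),
    }


def save_catalog(conditions: list[Condition], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"conditions": [c.to_dict() for c in conditions]}, fh,
                       sort_keys=False)


def load_catalog(path) -> list[Condition]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [Condition.from_dict(d) for d in raw["conditions"]]
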