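"""Calibration metrics, AP/CaT feature extraction and prediction quality.

Definitions used throughout the package:

* calibration error  = |log2(fitted / true)| per parameter
* calibration spread = sample SD of signed log2(fitted / true) across
  replicate GA runs
* APD90 = time from the upstroke (maximum dV/dt) to 90 % repolarization
  from the AP peak toward the preceding diastolic minimum.  Amplitudes are
  measured from the preceding diastolic minimum, so the same code serves
  raw (mV, mM) and min-max normalized traces.

All operations here are pure: nothing mutates simulation state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ConductanceSet, SolverSettings, apply_block, simulate
from .protocols import (
    Condition,
    DegenerateSignalError,
    Recording,
    extract_window,
    normalize,
)
from .constants import CONDUCTANCE_NAMES

__all__ = [
    "FeatureSet", "detect_upstrokes", "extract_features",
    "calibration_error", "calibration_spread", "mean_over_parameters",
    "prediction_error",
]

#: upstroke detection level for raw voltage traces (mV)
RAW_DETECTION_LEVEL = 0.0
#: detection level for min-max normalized traces
NORMALIZED_DETECTION_LEVEL = 0.5
#: refractory lockout between accepted upstrokes (ms)
DEFAULT_LOCKOUT_MS = 150.0


@dataclass
class FeatureSet:
    """Per-window AP/CaT features (window value = median over beats)."""

    apd90_ms: float
    ap_amplitude: float
    cat_amplitude: float
    beat_rate_hz: float
    n_beats: int
    quiescent: bool = False
    per_beat: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def quiescent_set(cls) -> "FeatureSet":
        return cls(apd90_ms=np.nan, ap_amplitude=np.nan, cat_amplitude=np.nan,
                   beat_rate_hz=0.0, n_beats=0, quiescent=True)


def detect_upstrokes(t_ms: np.ndarray, v: np.ndarray,
                     level: float | None = None,
                     normalized: bool = False,
                     lockout_ms: float = DEFAULT_LOCKOUT_MS) -> np.ndarray:
    """Indices of upstrokes: positive-slope crossings of the detection level
    with a refractory lockout, refined to the local maximum-dV/dt sample."""
    if level is None:
        level = NORMALIZED_DETECTION_LEVEL if normalized else RAW_DETECTION_LEVEL
    idx = np.where((v[:-1] < level) & (v[1:] >= level))[0]
    if idx.size == 0:
        return np.empty(0, dtype=int)
    keep = []
    for i in idx:
        if not keep or t_ms[i] - t_ms[keep[-1]] > lockout_ms:
            keep.append(int(i))
    # refine each crossing to the max-slope sample within +-20 ms
    dt = t_ms[1] - t_ms[0]
    half = max(1, int(round(20.0 / dt)))
    dv = np.gradient(v, t_ms)
    refined = []
    for i in keep:
        lo, hi = max(0, i - half), min(v.size, i + half)
        refined.append(lo + int(np.argmax(dv[lo:hi])))
    return np.asarray(refined, dtype=int)


def extract_features(rec: Recording,
                     lockout_ms: float = DEFAULT_LOCKOUT_MS) -> FeatureSet:
    """Beat-wise AP/CaT features of a recording; median over beats.

    A window with no detected beats returns the quiescent sentinel (features
    undefined, rate 0).  Features are invariant to a uniform time shift.
    """
    t, v, ca = rec.t_ms, rec.vm, rec.cai
    ups = detect_upstrokes(t, v, normalized=rec.normalized,
                           lockout_ms=lockout_ms)
    window_s = (t[-1] - t[0]) / 1000.0
    if ups.size == 0:
        return FeatureSet.quiescent_set()

    apds, ap_amps, cat_amps = [], [], []
    bounds = list(ups) + [v.size - 1]
    for b, (i, j) in enumerate(zip(bounds[:-1], bounds[1:])):
        # preceding diastolic minimum: from the previous upstroke (or window
        # start) up to this upstroke
        i0 = bounds[b - 1] if b > 0 else 0
        dia_v = float(np.min(v[i0:i + 1]))
        dia_ca = float(np.min(ca[i0:i + 1]))
        seg_v = v[i:j + 1]
        seg_t = t[i:j + 1]
        pk = int(np.argmax(seg_v))
        amp = float(seg_v[pk] - dia_v)
        if amp <= 0:
            continue
        ap_amps.append(amp)
        cat_amps.append(float(np.max(ca[i:j + 1]) - dia_ca))
        level90 = seg_v[pk] - 0.9 * amp
        below = np.where(seg_v[pk:] <= level90)[0]
        if below.size:
            apds.append(float(seg_t[pk + below[0]] - seg_t[0]))
    if not ap_amps:
        return FeatureSet.quiescent_set()
    return FeatureSet(
        apd90_ms=float(np.median(apds)) if apds else np.nan,
        ap_amplitude=float(np.median(ap_amps)),
        cat_amplitude=float(np.median(cat_amps)),
        beat_rate_hz=ups.size / window_s,
        n_beats=int(ups.size),
        per_beat={
            "apd90_ms": np.asarray(apds),
            "ap_amplitude": np.asarray(ap_amps),
            "cat_amplitude": np.asarray(cat_amps),
            "upstroke_ms": t[ups],
        },
    )


# ---------------------------------------------------------------------------
# parameter metrics
# ---------------------------------------------------------------------------

def _log2_ratio(fitted: ConductanceSet, truth: ConductanceSet) -> np.ndarray:
    f = fitted.to_vector()
    tr = truth.to_vector()
    if np.any(f <= 0) or np.any(tr <= 0):
        raise ValueError("multipliers must be positive for log2 ratios")
    return np.log2(f / tr)


def calibration_error(fitted: ConductanceSet,
                      truth: ConductanceSet) -> dict[str, float]:
    """|log2(fitted / true)| per parameter."""
    return dict(zip(CONDUCTANCE_NAMES,
                    np.abs(_log2_ratio(fitted, truth)).tolist()))


def calibration_spread(fitted_sets: list[ConductanceSet],
                       truth: ConductanceSet) -> dict[str, float]:
    """Sample SD (n-1) of signed log2(fitted / true) across replicate runs.

    Invariant to the truth values themselves (a translation in log space).
    """
    if len(fitted_sets) < 2:
        raise ValueError("calibration spread needs at least 2 runs")
    ratios = np.stack([_log2_ratio(fs, truth) for fs in fitted_sets])
    return dict(zip(CONDUCTANCE_NAMES, ratios.std(axis=0, ddof=1).tolist()))


def mean_over_parameters(per_parameter: dict[str, float]) -> float:
    """Unweighted mean over the 16 fitted parameters."""
    return float(np.mean([per_parameter[n] for n in CONDUCTANCE_NAMES]))


# ---------------------------------------------------------------------------
# prediction quality
# ---------------------------------------------------------------------------

def _ratio_apd(fs: FeatureSet) -> float:
    # APD90 normalized to AP amplitude, the scale-free quantity compared
    # across raw and normalized calibrations
    return fs.apd90_ms / fs.ap_amplitude


def prediction_error(calibrated: ConductanceSet, truth: ConductanceSet,
                     perturbation: dict[str, float], cond: Condition,
                     solver: SolverSettings | None = None,
                     duration_s: float | None = None,
                     normalized: bool = True) -> dict:
    """How well a calibrated cell predicts the true cell's response to a
    perturbation (e.g. ``{"I_Kr": 0.30}``).

    Simulates both cells with and without the perturbation, compares
    amplitude-normalized APD90 (percent error), the baseline-to-perturbed
    APD90 change (percent error, guarded when the true change is < 1 ms),
    and the trace MSE under the perturbed condition.
    """
    solver = solver or SolverSettings()
    out: dict = {"flags": []}
    recs: dict[tuple[str, bool], Recording] = {}
    feats: dict[tuple[str, bool], FeatureSet] = {}
    for who, cs in (("truth", truth), ("calibrated", calibrated)):
        for perturbed in (False, True):
            cell = apply_block(cs, perturbation) if perturbed else cs
            traj = simulate(cell, cond, duration_s=duration_s, solver=solver)
            rec = extract_window(traj, cond)
            if normalized:
                try:
                    rec = normalize(rec)
                except DegenerateSignalError:
                    out["flags"].append(f"degenerate:{who}:{perturbed}")
            recs[(who, perturbed)] = rec
            feats[(who, perturbed)] = extract_features(rec)

    if any(f.quiescent for f in feats.values()):
        out["flags"].append("arrhythmic-or-quiescent-trace")

    def pct(a, b):
        return 100.0 * (a - b) / b

    ft_base, ft_pert = feats[("truth", False)], feats[("truth", True)]
    fc_base, fc_pert = feats[("calibrated", False)], feats[("calibrated", True)]
    if ft_pert.quiescent or fc_pert.quiescent:
        out["apd90_pct_error"] = np.nan
    else:
        out["apd90_pct_error"] = pct(_ratio_apd(fc_pert), _ratio_apd(ft_pert))

    if (not perturbation or ft_pert.quiescent or ft_base.quiescent
            or fc_pert.quiescent or fc_base.quiescent):
        out["delta_apd90_pct_error"] = np.nan
        out["flags"].append("delta-undefined")
    else:
        d_true = ft_pert.apd90_ms - ft_base.apd90_ms
        d_cal = fc_pert.apd90_ms - fc_base.apd90_ms
        if abs(d_true) < 1.0:
            out["delta_apd90_pct_error"] = np.nan
            out["flags"].append("delta-below-guard")
        else:
            out["delta_apd90_pct_error"] = pct(d_cal, d_true)

    rt, rc = recs[("truth", True)], recs[("calibrated", True)]
    out["trace_mse"] = float(
        np.mean((rt.vm - rc.vm) ** 2) + np.mean((rt.cai - rc.cai) ** 2))
    return out
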