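"""Rule-based arrhythmia-dynamics classification and the IKr block
tolerance threshold.

The classifier assigns exactly one primary label per recording:

* ``cessation`` -- no upstrokes in the window;
* ``afterdepolarization`` -- a secondary positive-slope Vm deflection of at
  least 5 mV (raw) / 0.05 (normalized) during repolarization (EAD) or
  diastole (DAD), or sustained low-amplitude oscillation around a
  depolarized plateau without full repolarization (EAD-dominated dynamics;
  Torsades-like behavior at the single-cell level maps here);
* ``alternans`` -- consecutive-beat APD90 alternating by >= 5 % of the mean
  APD90 for at least two cycles;
* ``tachycardia`` -- spontaneous rate above twice the cell's baseline rate,
  or extra non-stimulated upstrokes under pacing;
* ``normal`` otherwise.

The rule thresholds are this package's own operational definitions (exposed
as arguments), chosen to be robust on the baseline model.

The IKr block tolerance threshold of a cell is the lowest fractional IKr
block whose steady-state dynamics are non-normal, located by a coarse 5 %
upward scan refined by bisection; every level is simulated from the fresh
reference initial state so the threshold is a property of the level, not of
the scan path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .evaluation import FeatureSet, detect_upstrokes, extract_features
from .model_core import ConductanceSet, SolverSettings, simulate
from .protocols import Condition, Recording, extract_window

__all__ = [
    "ArrhythmiaLabel", "ThresholdResult", "classify",
    "ikr_block_threshold", "threshold_prediction_metrics",
]

log = logging.getLogger(__name__)

LABELS = ("normal", "afterdepolarization", "alternans", "cessation",
          "tachycardia")


@dataclass
class ArrhythmiaLabel:
    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def is_normal(self) -> bool:
        return self.label == "normal"


@dataclass
class ThresholdResult:
    """Lowest fractional IKr block (percent) producing arrhythmia dynamics."""

    threshold_pct: float
    triggering_label: str
    resolution_pct: float
    levels: dict[float, str]
    flags: list[str] = field(default_factory=list)

    @property
    def tolerant_at_full_block(self) -> bool:
        return "tolerant at full block" in self.flags


def _deflections(seg_v: np.ndarray, min_amp: float) -> int:
    """Count trough -> rise >= min_amp -> turn-down events in a segment.

    A rise that runs into the segment end (the next upstroke, or the normal
    pacemaker depolarization into it) is not a deflection; a genuine EAD/DAD
    is a hump that rises and falls again within the segment.
    """
    count = 0
    k = 0
    n = seg_v.size
    while k + 2 < n:
        if seg_v[k + 1] < seg_v[k]:
            m = k + 1
            while m + 1 < n and seg_v[m + 1] <= seg_v[m]:
                m += 1
            trough = seg_v[m]
            r = m
            while r + 1 < n and seg_v[r + 1] >= seg_v[r]:
                r += 1
            if r < n - 1 and seg_v[r] - trough >= min_amp:
                count += 1
            k = r + 1
        else:
            k += 1
    return count


def classify(rec: Recording, baseline: FeatureSet | None = None,
             deflection_mV: float = 5.0, deflection_norm: float = 0.05,
             alternans_frac: float = 0.05,
             tachy_ratio: float = 2.0) -> ArrhythmiaLabel:
    """Deterministic rule-based label for a 5 s recording.

    ``baseline`` supplies the cell's unperturbed features for the
    tachycardia and repolarization-failure rules; without it those rules
    fall back to absolute raw-voltage criteria.
    """
    t, v = rec.t_ms, rec.vm
    ups = detect_upstrokes(t, v, normalized=rec.normalized)
    window_s = (t[-1] - t[0]) / 1000.0
    if ups.size == 0:
        return ArrhythmiaLabel("cessation", {"n_beats": 0})

    min_amp = deflection_norm if rec.normalized else deflection_mV
    feats = extract_features(rec)

    # failure to repolarize: oscillation around a depolarized plateau
    if baseline is not None and not baseline.quiescent:
        small = (not feats.quiescent
                 and feats.ap_amplitude < 0.5 * baseline.ap_amplitude)
    else:
        small = (not rec.normalized) and float(np.min(v)) > -50.0
    if small:
        return ArrhythmiaLabel("afterdepolarization", {
            "mode": "plateau-oscillation",
            "window_min_v": float(np.min(v)),
            "ap_amplitude": feats.ap_amplitude,
        })

    # EAD / DAD: secondary deflections between one upstroke's peak and the
    # next upstroke
    bounds = list(ups) + [v.size - 1]
    n_ead = 0
    for i, j in zip(bounds[:-1], bounds[1:]):
        seg = v[i:j + 1]
        pk = int(np.argmax(seg))
        # exclude the upstroke itself and the next upstroke's foot
        tail = seg[pk:]
        if tail.size > 5:
            n_ead += _deflections(tail[:-2], min_amp)
    if n_ead > 0:
        return ArrhythmiaLabel("afterdepolarization",
                               {"mode": "EAD/DAD", "count": n_ead})

    rate = ups.size / window_s
    paced = rec.pacing is not None and rec.pacing.is_paced
    if paced:
        expected = window_s * rec.pacing.frequency_hz
        if ups.size > expected + 1:
            return ArrhythmiaLabel("tachycardia", {
                "n_beats": int(ups.size), "expected": float(expected)})
    elif baseline is not None and baseline.beat_rate_hz > 0:
        if rate > tachy_ratio * baseline.beat_rate_hz:
            return ArrhythmiaLabel("tachycardia", {
                "rate_hz": rate, "baseline_hz": baseline.beat_rate_hz})

    apds = feats.per_beat.get("apd90_ms", np.empty(0))
    if apds.size >= 4:
        d = np.diff(apds)
        thr = alternans_frac * float(np.mean(apds))
        alt_run = 0
        for k in range(len(d) - 1):
            if (abs(d[k]) >= thr and abs(d[k + 1]) >= thr
                    and np.sign(d[k]) != np.sign(d[k + 1])):
                alt_run += 1
        if alt_run >= 2:
            return ArrhythmiaLabel("alternans", {
                "apds_ms": apds.tolist(),
                "alternation_frac": float(np.mean(np.abs(d)) / np.mean(apds)),
            })

    return ArrhythmiaLabel("normal", {"n_beats": int(ups.size),
                                      "rate_hz": rate})


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

def _label_at(cs: ConductanceSet, cond: Condition, pct: float,
              baseline: FeatureSet | None, solver: SolverSettings,
              duration_s: float | None) -> ArrhythmiaLabel:
    blocked = cond.with_blocks({"I_Kr": pct / 100.0})
    traj = simulate(cs, blocked, duration_s=duration_s, solver=solver)
    rec = extract_window(traj, blocked)
    lab = classify(rec, baseline=baseline)
    log.info("threshold scan: %.1f%% IKr block -> %s", pct, lab.label)
    return lab


def ikr_block_threshold(cs: ConductanceSet, cond: Condition,
                        resolution_pct: float = 1.0,
                        solver: SolverSettings | None = None,
                        duration_s: float | None = None,
                        coarse_step_pct: float = 5.0) -> ThresholdResult:
    """Scan IKr block upward (coarse pass then bisection) for the lowest
    level with non-normal dynamics.

    Every level runs from the fresh reference initial state for the full
    condition duration.  The cell must be normal at 0 % block.
    """
    solver = solver or SolverSettings()
    levels: dict[float, str] = {}

    base_traj = simulate(cs, cond, duration_s=duration_s, solver=solver)
    base_rec = extract_window(base_traj, cond)
    baseline = extract_features(base_rec)
    lab0 = classify(base_rec, baseline=None)
    levels[0.0] = lab0.label
    if not lab0.is_normal:
        raise ValueError(
            f"cell is already {lab0.label} at 0% block under "
            f"{cond.label!r}; threshold undefined")

    lo, hi, hi_label = 0.0, None, None
    pct = coarse_step_pct
    while pct <= 100.0 + 1e-9:
        lab = _label_at(cs, cond, min(pct, 100.0), baseline, solver,
                        duration_s)
        levels[round(min(pct, 100.0), 6)] = lab.label
        if not lab.is_normal:
            hi, hi_label = min(pct, 100.0), lab.label
            break
        lo = min(pct, 100.0)
        pct += coarse_step_pct
    if hi is None:
        return ThresholdResult(100.0, "normal", resolution_pct, levels,
                               flags=["tolerant at full block"])

    while hi - lo > resolution_pct + 1e-9:
        mid = round((lo + hi) / 2.0 / resolution_pct) * resolution_pct
        if mid <= lo or mid >= hi:
            break
        lab = _label_at(cs, cond, mid, baseline, solver, duration_s)
        levels[round(mid, 6)] = lab.label
        if lab.is_normal:
            lo = mid
        else:
            hi, hi_label = mid, lab.label
    return ThresholdResult(float(hi), hi_label, resolution_pct,
                           dict(sorted(levels.items())))


def threshold_prediction_metrics(predicted: dict[str, list[float]],
                                 truth: dict[str, float]) -> dict:
    """Accuracy of predicted thresholds against the true thresholds.

    ``predicted`` maps cell id to the thresholds of that cell's replicate
    calibrated models; ``truth`` maps cell id to the true threshold.
    Returns signed per-run errors (percentage points), the Spearman rank
    correlation between true and mean predicted thresholds across cells,
    and the correlation between the true threshold and the mean absolute
    prediction error.
    """
    cells = sorted(truth)
    errors = {c: [p - truth[c] for p in predicted[c]] for c in cells}
    out: dict = {"errors_pct_points": errors, "flags": []}
    mean_pred = np.array([np.mean(predicted[c]) for c in cells])
    truths = np.array([truth[c] for c in cells])
    mean_abs_err = np.array([np.mean(np.abs(errors[c])) for c in cells])
    if len(cells) < 3:
        out["rank_correlation"] = np.nan
        out["error_correlation"] = np.nan
        out["flags"].append("fewer than 3 cells: rank correlation undefined")
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant input -> nan is fine
            out["rank_correlation"] = float(
                spearmanr(truths, mean_pred).statistic)
            out["error_correlation"] = float(
                spearmanr(truths, mean_abs_err).statistic)
    return out
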