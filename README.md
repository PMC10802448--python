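# ipsctwin

Cell-preparation-specific **digital twins of iPSC-derived cardiomyocytes**
(iPSC-CMs), built by calibrating the maximal-conductance parameters of an
electrophysiology model to action-potential (AP) and calcium-transient (CaT)
recordings.

iPSC-CM preparations vary widely between cell lines, differentiation
batches and labs. A single published "average" model cannot represent that
heterogeneity, and patch-clamping every current of every preparation does
not scale. This package implements the alternative: record normalized
fluorescence AP/CaT waveforms of a preparation under a few cheap condition
changes (buffer Ca²⁺, pacing rate, partial channel block), then let a
genetic algorithm (GA) find the conductance scale factors of a
mechanistic ODE model that reproduce those waveforms. The calibrated model
predicts cell-specific responses to perturbations it never saw — most
importantly IKr (hERG) block, the dominant mechanism of drug-induced
arrhythmia.

## The model and the calibration problem

The simulator (`ipsctwin.model_core`) is a single-cell iPSC-CM ODE model —
membrane potential, intracellular and sarcoplasmic-reticulum Ca²⁺, dynamic
Na⁺/K⁺, and Hodgkin–Huxley gating — parameterized by 16 maximal-conductance
scale factors G_X (G_Na, G_CaL, G_CaT, G_to, G_Kr, G_Ks, G_K1, G_f, G_NaK,
G_NaCa, G_PCa, G_bNa, G_bCa, G_SERCA, G_rel, G_SRleak), with multiplier 1
everywhere defining the baseline cell. The baseline beats spontaneously in
the 0.3–1.0 Hz automaticity band of human iPSC-CMs and follows 1–2 Hz
pacing (60 pA/pF, 1 ms pulses). The kinetic parameterization is a
documented synthetic stand-in assembled from standard human-myocyte
formulations (see `docs/methods.md` and
`src/ipsctwin/data/model_constants.yaml`).

A calibration instance is:

* a **protocol** — an ordered chain of conditions (e.g. 1.0 mM Ca²⁺ @ 1 Hz →
  1.8 mM @ 1 Hz → 1.8 mM @ 1.25 Hz), each simulated for 5 min with state
  carry-over, keeping the final 5 s at 0.1 ms resolution, optionally min–max
  normalized to emulate fluorescence;
* a **fitness** — the mean-squared error between candidate and target
  traces summed over channels (V, Ca²⁺ or both) and conditions;
* a **GA** — tournament selection, blend crossover and Gaussian mutation in
  log-multiplier space over the box [0.1, 10], with elitism; replicate runs
  from independent initial populations quantify how well each parameter is
  constrained.

Calibrations are scored by parameter error `|log2(fitted/true)|`, the
replicate spread of `log2(fitted/true)`, and prediction of held-out
responses — 30 % IKr block traces, and the **IKr block tolerance
threshold**: the lowest fractional IKr block at which the cell's dynamics
become arrhythmic (afterdepolarizations, alternans, beating cessation,
tachycardia), located by a coarse scan plus bisection. A multivariable
regression over a log-normally varied population ranks the conductances by
their influence on APD90, CaT amplitude and the block threshold.

## Worked example

```python
from ipsctwin import (ConductanceSet, simulate, extract_window,
                      extract_features, classify)
from ipsctwin.population import physiological_condition
from ipsctwin.arrhythmia import ikr_block_threshold

# a hypothetical preparation: 30% less IKr, 20% more ICaL than baseline
cell = ConductanceSet.baseline().replace(G_Kr=0.7, G_CaL=1.2)
cond = physiological_condition(duration_s=60.0)   # 300.0 for full runs
rec = extract_window(simulate(cell, cond), cond)
f = extract_features(rec)
print(f"rate      {f.beat_rate_hz:.1f} Hz")
print(f"APD90     {f.apd90_ms:.1f} ms")
print(f"CaT amp   {f.cat_amplitude*1e3:.3f} uM")
print(f"label     {classify(rec).label}")
thr = ikr_block_threshold(cell, cond, resolution_pct=1.0, duration_s=60.0)
print(f"IKr block tolerance threshold: {thr.threshold_pct:.0f}% "
      f"({thr.triggering_label})")
```

prints

```
rate      0.6 Hz
APD90     640.9 ms
CaT amp   1.114 uM
label     normal
IKr block tolerance threshold: 39% (afterdepolarization)
```

The reduced-IKr cell beats normally at 0.6 Hz with a prolonged APD90, but
loses its normal rhythm at 39 % additional IKr block — far more
susceptible than the baseline cell (threshold ≈ 60 %). Cell-to-cell
differences of exactly this kind are what the calibrated twins are built
to predict.

The same pipeline is scriptable from the shell:

```bash
ipsctwin generate  --out runs/ds --n-cells 4 --seed 1          # dataset
ipsctwin calibrate --dataset runs/ds/dataset_normalized.h5 \
                   --protocol optimized-3 --replicates 10 \
                   --seed 1 --out runs/cal                      # GA fits
ipsctwin validate  --calibration runs/cal \
                   --dataset runs/ds/dataset_normalized.h5 \
                   --out runs/val                               # 30% IKr block
ipsctwin threshold --cells runs/ds/dataset_raw.h5 --out runs/thr
ipsctwin sensitivity --n-cells 300 --out runs/sens
```

(add `--test-scale` to any command for quick 30 s pre-equilibration runs).

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch — samples and
filters a fresh synthetic population, builds the normalized 3-condition
dataset, calibrates two ground-truth cells with replicate GA runs, scores
parameter error/spread and the held-out 30 % IKr-block prediction,
computes IKr block tolerance thresholds at 1 % resolution, and fits the
population sensitivity regression for APD90 — then writes its result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
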