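# Methods

This note documents the science and the numerical choices behind
`ipsctwin`: the cell model, the synthetic-data generator, the genetic
algorithm, the arrhythmia classifier, the sensitivity regression and the
fluorescence preprocessing chain — including what each green test does and
does not establish.

## 1. The cell model

### Structure

`ipsctwin.model_core` integrates a single-cell iPSC-CM model with 20 state
variables: membrane potential Vm (mV); free cytosolic and
sarcoplasmic-reticulum (SR) Ca²⁺, intracellular Na⁺ and K⁺ (mM, with
rapid-buffering corrections for both Ca²⁺ pools); and 15 Hodgkin–Huxley
gates. Membrane currents (pA/pF): fast Na⁺ (I_Na), L-type Ca²⁺ with
voltage- and Ca²⁺-dependent inactivation (I_CaL, GHK driving force),
T-type Ca²⁺ (I_CaT), transient-outward (I_to), rapid and slow delayed
rectifier (I_Kr, I_Ks), inward rectifier (I_K1), hyperpolarization-activated
funny current (I_f, mixed Na⁺/K⁺), Na⁺/K⁺ pump, Na⁺/Ca²⁺ exchanger,
sarcolemmal Ca²⁺ pump and Na⁺/Ca²⁺ background leaks. SR fluxes: SERCA
uptake, RyR release with Ca²⁺-dependent activation/inactivation, and a
passive leak. Sixteen maximal conductances/fluxes scale these terms; they
are the calibration targets, addressed by dimensionless multipliers with
1.0 = baseline.

### Provenance — a synthetic stand-in parameterization

The published iPSC-CM models this pipeline is designed around could not be
obtained in this build environment. The simulator therefore implements
their *interface and current structure* with kinetic formulations assembled
from standard, widely published human-myocyte components (Luo–Rudy-style
I_Na gating; ten-Tusscher-style K⁺ currents, pumps, exchanger and Ca²⁺
handling; a Paci-style funny current; a Kurata-style I_CaT), plus two
deliberate iPSC-specific modifications:

* **Very small I_K1 and a negatively shifted I_Kr activation.** iPSC-CMs
  express little Kir2.1; their maximum diastolic potential (MDP) is
  maintained substantially by hERG current, so hERG block depolarizes the
  MDP and can silence automaticity. The Xr1 activation variable is shifted
  −20 mV so I_Kr keeps a small standing diastolic component.
* **Smooth Ca²⁺-dependent time constants** for the I_CaL fCa gate and the
  RyR inactivation gate (fast inactivation at systolic Ca²⁺, slow recovery
  at diastolic Ca²⁺), replacing hard conditional switches that defeat
  stiff multistep integrators.

The 16 baseline conductance values were tuned **once**, before any
pipeline or test was built, to the published iPSC-CM phenotype targets:
spontaneous rate inside 0.3–1.0 Hz (baseline ≈ 0.7 Hz), MDP ≈ −78 mV,
AP amplitude ≈ 95 mV, APD90 ≈ 400–470 ms, 1:1 capture at 1–2 Hz field
pacing with 60 pA/pF × 1 ms pulses, steady state within a 300 s run,
physiological responses along the condition axes (buffer Ca²⁺ 1.0/1.8/2.7
mM, I_CaL block, I_Kr up/down), and loss of normal automaticity under
strong I_Kr block (baseline tolerance threshold ≈ 60 %). The frozen values
and the reference initial state (the baseline cell's state after 300 s of
spontaneous activity) live in `src/ipsctwin/data/model_constants.yaml`,
version-tagged.

Consequences for interpretation: quantitative agreement with any specific
published parameter set is **not** claimed and not tested; all pipeline
results (parameter recovery, protocol orderings, threshold spreads) are
statements about this model family. Those are exactly the statements the
pipeline is designed to make, because the ground truth is always a cell of
the same family.

### Numerics

The RHS is a numba-compiled scalar kernel. Integration uses LSODA (via
`scipy.integrate.odeint`, vector atol: 10⁻⁶ on Vm/Na⁺/K⁺, 10⁻¹⁰ on
cytosolic Ca²⁺, 10⁻⁸ elsewhere; rtol 10⁻⁶) with an automatic BDF
(`solve_ivp`) retry of any failed segment. The time axis is split at every
stimulus-pulse edge and into ≤ 2 s chunks; the stimulus on/off state is
passed to the kernel as a per-segment flag, so the RHS is continuous in
time within every solver call (square pulses are represented exactly, and
LSODA never steps across a discontinuity). Halving the tolerances changes
the baseline APD90 by < 1 ms (asserted in the acceptance suite). A
wall-clock limit per simulation converts runaway integrations into a
`SimulationTimeout` that the GA maps to the worst fitness. Output is
recorded at 1 ms, with the final 6 s at 0.1 ms for windowing.

## 2. Protocols, recordings, normalization

A `Condition` = buffer Ca²⁺, pacing spec (spontaneous or square-pulse
train), fractional channel blocks, and a duration (default 300 s, the
time the baseline model needs to reach steady state). A `Protocol` chains
conditions with state carry-over (condition *k+1* starts from *k*'s final
state), emulating a preparation moved through solution changes. Each
condition yields a `Recording`: the final 5 s interpolated linearly onto a
uniform 0.1 ms grid (50,001 samples). Min–max normalization per channel
per recording emulates fluorescence readouts; it is idempotent and
invariant to affine transforms of the raw signals, which is the premise
that lets uncalibrated dyes stand in for patch-clamp data. A constant
channel raises a degenerate-signal error (dead trace) rather than
producing NaNs.

The shipped 19-condition catalog spans buffer Ca²⁺ {1.0, 1.8, 2.7} mM ×
pacing {spontaneous, 1, 1.25, 1.5, 2 Hz} × I_CaL block {0, 25, 50 %};
I_Kr-block conditions are deliberately excluded and reserved for
validation. The catalog is editable (YAML round-trip); the named
3-condition protocols (`optimized-3`, `mixed-3`, axis protocols, and their
1- and 2-condition subsets) are built from it.

## 3. Synthetic populations

Heterogeneous "cell lines" are drawn by scaling each of the 16 baseline
conductances with an independent log-normal multiplier of median 1 and
natural-log SD σ = 0.2 (σ is configurable; the log base is a documented
choice since "spread" alone does not fix it). Populations are filtered for
spontaneous rate within [0.3, 1.0] Hz under the physiological unperturbed
condition — with σ = 0.2 roughly 90 % of draws pass. Dataset cells are
simulated independently under every catalog condition from the reference
initial state (each condition runs 300 s to its own steady state, so
chained and independent simulation coincide there); the GA, in contrast,
simulates candidate protocols chained, exactly as the data-generating
protocol would be run on a dish. Ground-truth multipliers are stored
beside, never inside, the recordings.

The generator produces **clean, noise-free traces**: no photon noise,
motion artifact, dye bleaching or cell-to-cell averaging. A green
calibration test therefore establishes identifiability under ideal data;
robustness to measurement noise enters only through the fluorescence
preprocessing chain (§7).

## 4. Genetic algorithm

Genomes are natural-log multipliers of the free parameters (default: all
16), initialized log-uniformly in [ln 0.1, ln 10]. Generational loop with
tournament selection (size 3), per-pair blend (BLX-α, α = 0.5) crossover
at rate 0.9, per-gene Gaussian mutation (σ = 0.1 log units) at rate 0.1,
and 2 elites; 20 generations and population 200 at full scale, 10
replicates per protocol per cell with seeds `base_seed + k`. These GA
internals are this package's own standard choices (the defaults are
exposed in `GAConfig`); elitism guarantees a non-increasing best-so-far
fitness, asserted per run.

Fitness = Σ over conditions and included channels of the per-sample MSE on
the common 0.1 ms grid. Channels are *not* variance-reweighted; on raw
(mV, mM) data the voltage channel therefore dominates a two-channel
fitness, which is one reason the pipeline's primary mode is normalized
data, where both channels live on [0, 1]. For spontaneous conditions the
candidate trace is circularly aligned to the target by the
cross-correlation-optimal lag of the voltage channel before the MSE, since
spontaneous phase is arbitrary; paced conditions compare in absolute time.
Any failure mode — integration failure, timeout, quiescent trace (< 10 mV
peak-to-peak), degenerate normalization — scores the sentinel worst
fitness (10¹²) so the GA loop is total; if an entire initial population is
at the sentinel, a diagnostic error points at bounds/protocol mismatch.

## 5. Evaluation metrics

Per parameter: calibration error `|log2(fitted/true)|`; calibration spread
= sample SD (n−1) of signed `log2(fitted/true)` across replicate runs.
Aggregation over parameters is the unweighted mean. AP/CaT features are
measured per beat and summarized by the median (robust to one odd beat):
upstroke = maximum-dV/dt sample near a threshold crossing (0 mV raw, 0.5
normalized, 150 ms lockout), AP amplitude = peak − preceding diastolic
minimum, APD90 = upstroke → 90 % repolarization toward that minimum
(amplitude-referenced, so identical code serves raw and normalized
traces), CaT amplitude likewise. Held-out prediction quality compares
amplitude-normalized APD90 (percent error), the baseline→block APD90
change (guarded when the true change is < 1 ms), and the trace MSE under
the blocked condition.

## 6. Arrhythmia classification and the block-tolerance threshold

The five labels and their operational rules (package-defined; the
literature states the phenomena, not detection thresholds):

* **cessation** — no upstrokes in the 5 s window;
* **afterdepolarization** — a trough→rise→turn-down deflection ≥ 5 mV
  (raw; 0.05 normalized) between an AP peak and the next upstroke (EAD
  during repolarization, DAD during diastole; a rise that runs directly
  into the next upstroke is pacemaker depolarization, not a DAD), or
  sustained oscillation around a depolarized plateau without full
  repolarization (window minimum above −50 mV raw, or AP amplitude below
  half the cell's baseline amplitude) — the model's dominant response to
  strong I_Kr block, and the single-cell face of torsadogenic dynamics;
* **alternans** — ≥ 2 consecutive alternating-sign beat-to-beat APD90
  differences, each ≥ 5 % of the mean APD90;
* **tachycardia** — spontaneous rate > 2× the cell's baseline rate, or
  more upstrokes than stimuli (+1 margin) under pacing;
* **normal** otherwise. Exactly one primary label is returned, with
  evidence.

The I_Kr block tolerance threshold scans block level upward in 5 % steps
and bisects to the requested resolution (1 % by default). Every level is
simulated from the fresh reference initial state for the full condition
duration, so the threshold is a property of the block level, not of the
scan path; monotonic consistency (normal below, non-normal at threshold)
is asserted on every result. A cell still normal at 100 % is flagged
"tolerant at full block". The baseline cell's threshold under the
spontaneous physiological condition is ≈ 60 %; across a σ = 0.2 filtered
population thresholds span roughly 35–75 %, with low-G_Kr/high-G_CaL
draws at the susceptible end.

## 7. Sensitivity regression

X = column-standardized log2 multipliers of the population cells, Y =
column-standardized phenotypes (APD90, CaT amplitude, beat rate,
optionally the block threshold) under a stated condition (default:
1.8 mM Ca²⁺, 1 Hz pacing); quiescent/failed cells are excluded with
logged reasons. Ordinary least squares is the default — the design matrix
of independent log-normal draws is well-conditioned, and OLS keeps
coefficients directly interpretable; PLS is available as an option and
agrees with OLS on planted effects. Requires ≥ 3 rows per column; rank
deficiency and zero-variance columns are errors naming the offender.
Parameters are ranked per output by |β| (ties broken by canonical
parameter order) into top-k/bottom-k groups (k = 4), and calibration
error/spread values are grouped accordingly for the constraint report.
On this model, G_Kr, G_NaK, G_CaL and G_NaCa dominate APD90 (R² ≈ 0.97).

## 8. Fluorescence preprocessing

Order-fixed chain for optical recordings (native rate ~125 samples/s):

1. baseline-drift removal — grayscale erosion with a structuring width of
   1.5× the expected beat period, closed by a dilation of the same width
   (a morphological opening; the bare sliding minimum carries a half-window
   bias under linear drift) and re-anchored below the signal;
2. median filter (default 5 samples, reflected edges) for impulse noise;
3. final-window extraction, linear resampling to the 0.1 ms grid, min–max
   normalization.

The output `Recording` is indistinguishable from a synthetic normalized
recording, so calibration code cannot tell data provenance — the property
that lets in-vitro data drive the same GA. A simulated trace corrupted
with linear drift and impulse spikes keeps its APD90 within 5 ms through
the chain (acceptance suite). The hypo-Ca²⁺ (1.0 mM) + 2 Hz condition is
never passed to calibration; it is the in-vitro validation split.

## 9. Test and acceptance scales

The standard protocol duration is 300 s per condition. Unit tests run at
8–30 s pre-equilibration; the acceptance suite uses 12–40 s for GA-based
checks and 300 s where the criterion is about the steady state itself
(self-consistency, steady-state and tolerance invariants). Stochastic
GA-based orderings (channel ablation, protocol richness) run at smoke
scale — 3 replicates, population 16–20, 8–10 generations, fixed seeds —
and the protocol-richness comparison searches the 5 conductances the
protocol axes act on directly (G_Kr, G_CaL, G_K1, G_NaK, G_CaT) with the
rest clamped to truth, because a 16-dimensional search at a few hundred
evaluations measures optimizer noise rather than protocol
identifiability. Full-scale runs (population 200, 20 generations, 10
replicates, 300 s conditions, 16 free parameters) use the same code paths
via `GAConfig` and condition durations and are overnight-scale on one CPU.

## 10. Known limitations

* The model parameterization is a stand-in (§1); absolute APD/CaT values
  and threshold locations are model-family properties.
* Clean synthetic data only; no measurement-noise model beyond the
  preprocessing round trip.
* Conductance multipliers are sampled independently (no co-regulation),
  and kinetic (non-conductance) parameters are never calibrated.
* Torsades de Pointes is a tissue-level phenomenon; here it can only map
  to afterdepolarization-driven single-cell dynamics.
* Raw-data (non-normalized) two-channel fitting is voltage-dominated by
  construction (§4).
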