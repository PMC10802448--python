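# Versioned constants of the ipsctwin iPSC-CM model.
#
# SYNTHETIC STAND-IN PARAMETERIZATION.  This is not a transcription of any
# single published model.  The current structure (16 scalable maximal
# conductances, SR Ca handling, funny current, dynamic Nai/Ki) mirrors the
# iPSC-CM models used for digital-twin calibration; kinetic formulations are
# assembled from standard human-myocyte formulations and the baseline
# conductances below were calibrated once to the iPSC-CM phenotype targets
# (spontaneous rate in 0.3-1.0 Hz, steady state within 300 s, 1:1 capture at
# 1-2 Hz pacing with 60 pA/pF x 1 ms pulses, loss of normal automaticity
# under strong IKr block).  See docs/methods.md.
version: "1.0"

# baseline maximal conductances / fluxes (multiplier 1.0 refers to these)
# units: most currents nS/pF-equivalent (pA/pF per mV); G_CaL is a GHK
# permeability scale; G_NaCa and G_NaK scale pump/exchanger throughput;
# G_SERCA in mM/ms; G_SRleak in 1/ms; G_rel dimensionless flux scale.
conductances:
  G_Na: 9.0
  G_CaL: 0.8
  G_CaT: 0.18
  G_to: 0.12
  G_Kr: 0.12
  G_Ks: 0.02
  G_K1: 0.01
  G_f: 0.03
  G_NaK: 1.4
  G_NaCa: 400.0
  G_PCa: 0.15
  G_bNa: 0.0008
  G_bCa: 0.0006
  G_SERCA: 0.001
  G_rel: 1.0
  G_SRleak: 0.00008

# default extracellular milieu (mM)
extracellular:
  Cao: 1.8
  Nao: 140.0
  Ko: 5.4

# default stimulus for paced conditions
stimulus:
  amplitude_pa_per_pf: 60.0
  duration_ms: 1.0

# reference initial state: the baseline model's state after 300 s of
# spontaneous activity under the physiological unperturbed condition
# (1.8 mM Cao, no pacing), frozen at model version 1.0.
initial_state:
  V: -71.14962762
  Cai: 0.0001164268092
  CaSR: 2.215493603
  Nai: 8.385046634
  Ki: 118.5886447
  m: 0.01462764934
  h: 0.7572852574
  j: 0.8073759118
  d: 0.0002200834813
  f: 0.9052475281
  fCa: 1.0
  dT: 0.0005659911833
  fT: 0.8616503118
  Xr1: 0.5462806709
  Xr2: 0.3315886467
  Xs: 0.009011502323
  r: 2.470052717e-07
  s: 0.9999664241
  xf: 0.07015949966
  g: 0.9982406847
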