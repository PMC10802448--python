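"""Frozen model constants: parameter names, baselines, reference state.

The single source of truth is the versioned, human-readable
``data/model_constants.yaml`` shipped with the package.  Everything that
needs a name/index mapping for the ODE kernel imports it from here.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from . import _kernel as kernel

#: canonical order of the 16 maximal-conductance scale parameters; this order
#: matches ``p[0:16]`` of the kernel parameter vector and must never change.
CONDUCTANCE_NAMES: tuple[str, ...] = (
    "G_Na", "G_CaL", "G_CaT", "G_to", "G_Kr", "G_Ks", "G_K1", "G_f",
    "G_NaK", "G_NaCa", "G_PCa", "G_bNa", "G_bCa", "G_SERCA", "G_rel",
    "G_SRleak",
)

#: state-variable names in kernel order (Vm in mV, concentrations in mM,
#: gating variables dimensionless)
STATE_NAMES: tuple[str, ...] = (
    "V", "Cai", "CaSR", "Nai", "Ki", "m", "h", "j", "d", "f", "fCa",
    "dT", "fT", "Xr1", "Xr2", "Xs", "r", "s", "xf", "g",
)

#: names of membrane currents / SR fluxes in kernel output order
CURRENT_NAMES: tuple[str, ...] = (
    "I_Na", "I_CaL", "I_CaT", "I_to", "I_Kr", "I_Ks", "I_K1", "I_f",
    "I_NaK", "I_NaCa", "I_PCa", "I_bNa", "I_bCa", "I_stim",
    "J_SERCA", "J_rel", "J_SRleak",
)

#: map from a (blockable) current/flux name to the conductance it scales
CURRENT_TO_CONDUCTANCE: dict[str, str] = {
    "I_Na": "G_Na", "I_CaL": "G_CaL", "I_CaT": "G_CaT", "I_to": "G_to",
    "I_Kr": "G_Kr", "I_Ks": "G_Ks", "I_K1": "G_K1", "I_f": "G_f",
    "I_NaK": "G_NaK", "I_NaCa": "G_NaCa", "I_PCa": "G_PCa",
    "I_bNa": "G_bNa", "I_bCa": "G_bCa", "J_SERCA": "G_SERCA",
    "J_rel": "G_rel", "J_SRleak": "G_SRleak",
}

GATE_NAMES: tuple[str, ...] = STATE_NAMES[5:]


def _load() -> dict:
    text = (resources.files("ipsctwin") / "data" / "model_constants.yaml").read_text()
    raw = yaml.safe_load(text)
    cond = raw["conductances"]
    if set(cond) != set(CONDUCTANCE_NAMES):
        raise RuntimeError("constants file conductance names out of sync")
    if set(raw["initial_state"]) != set(STATE_NAMES):
        raise RuntimeError("constants file state names out of sync")
    return raw


_RAW = _load()

MODEL_VERSION: str = str(_RAW["version"])

#: baseline conductance values (what a multiplier of 1.0 refers to)
BASELINE_CONDUCTANCES: dict[str, float] = {
    name: float(_RAW["conductances"][name]) for name in CONDUCTANCE_NAMES
}

BASELINE_VECTOR: np.ndarray = np.array(
    [BASELINE_CONDUCTANCES[n] for n in CONDUCTANCE_NAMES]
)

#: default extracellular concentrations, mM
DEFAULT_CAO: float = float(_RAW["extracellular"]["Cao"])
DEFAULT_NAO: float = float(_RAW["extracellular"]["Nao"])
DEFAULT_KO: float = float(_RAW["extracellular"]["Ko"])

#: default pacing pulse
DEFAULT_STIM_AMPLITUDE: float = float(_RAW["stimulus"]["amplitude_pa_per_pf"])
DEFAULT_STIM_DURATION_MS: float = float(_RAW["stimulus"]["duration_ms"])

#: reference initial state (baseline model after 300 s spontaneous activity)
REFERENCE_INITIAL_STATE: np.ndarray = np.array(
    [float(_RAW["initial_state"][n]) for n in STATE_NAMES]
)

assert len(CONDUCTANCE_NAMES) == kernel.N_COND == 16
assert len(STATE_NAMES) == kernel.N_STATES
assert len(CURRENT_NAMES) == kernel.N_CURRENTS
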