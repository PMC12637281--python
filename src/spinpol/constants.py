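"""Physical constants and unit-conversion factors.

Internal unit system: magnetic field in mT, microwave/electron frequencies in
GHz, hyperfine couplings in MHz, times in s unless a result is documented
otherwise.  All values are CODATA (via :mod:`scipy.constants`) and fixed at
import time.
"""

from scipy.constants import h, k as k_B, physical_constants

#: Bohr magneton (J/T)
mu_B = physical_constants["Bohr magneton"][0]

#: Free-electron g value (positive convention)
g_electron = -physical_constants["electron g factor"][0]

#: Bohr magneton expressed as a frequency-per-field factor.  Numerically the
#: same in GHz/T and MHz/mT (~13.996), which is the form every field<->frequency
#: conversion below uses.
MU_B_MHZ_PER_MT = physical_constants["Bohr magneton in Hz/T"][0] * 1e-9

#: 13C gyromagnetic ratio gamma/2pi in MHz/T (fixed project convention).
GAMMA_13C_MHZ_PER_T = 10.7084

#: gamma/2pi in MHz/T for the isotopes the simulator knows about.
GYROMAGNETIC_MHZ_PER_T = {
    "13C": GAMMA_13C_MHZ_PER_T,
    "1H": 42.577478,
    "2H": 6.535902,
    "14N": 3.077706,
    "15N": -4.316,
}


def resonance_field_mT(g_eff: float, mw_frequency_GHz: float) -> float:
    """Electron resonance field B = h nu / (g mu_B), in mT."""
    return 1e3 * mw_frequency_GHz / (MU_B_MHZ_PER_MT * g_eff)


def resonance_frequency_GHz(g_eff: float, b_mT: float) -> float:
    """Electron resonance frequency nu = g mu_B B / h, in GHz."""
    return MU_B_MHZ_PER_MT * g_eff * b_mT * 1e-3
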