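"""Unit conversions for the internal nm / kT / pN system.

All model energies are expressed in units of the thermal energy kT and all
lengths in nanometres.  Forces therefore come out in kT/nm and are converted
to piconewtons with the factor ``kT_pN_nm(T)`` (≈4.11 pN·nm at 298 K).
The hydration pressure prefactor is quoted in the membrane-biophysics
literature in dyn/cm² and is converted once, at parameter construction.
"""

from __future__ import annotations

BOLTZMANN_J_PER_K = 1.380649e-23
"""Boltzmann constant, J/K (exact, SI 2019)."""

DEFAULT_TEMPERATURE_K = 298.0

DYN_PER_CM2_TO_PA = 0.1
PA_TO_J_PER_NM3 = 1e-27


def kT_joule(T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in joules at absolute temperature ``T``."""
    return BOLTZMANN_J_PER_K * T


def kT_pN_nm(T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in pN·nm at ``T`` (≈4.114 at 298 K)."""
    return kT_joule(T) * 1e21


def dyn_cm2_to_kT_nm3(p: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a pressure from dyn/cm² to kT/nm³."""
    return p * DYN_PER_CM2_TO_PA * PA_TO_J_PER_NM3 / kT_joule(T)


def kT_per_nm_to_pN(f: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a force (energy gradient) from kT/nm to pN."""
    return f * kT_pN_nm(T)
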