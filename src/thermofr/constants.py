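"""Physical constants and temperature-unit helpers.

All internal computation is carried out in Kelvin; degrees Celsius appear
only at I/O boundaries.  The Boltzmann constant and the two reference
temperatures are configuration, injected into every downstream stage,
because the feeding/metabolism equations are referenced to 283.15 K while
the assimilation-efficiency relation is referenced to 293.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in electron-volts per Kelvin.
BOLTZMANN_EV_K = 8.618e-5

#: Reference temperature (K) for feeding, mortality and metabolic rates
#: (10 degC, the mid-point of the experimental temperature range).
T0_K = 283.15

#: Reference temperature (K) for the assimilation-efficiency relation.
T0_STAR_K = 293.15

ZERO_CELSIUS_K = 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants shared by the whole pipeline."""

    boltzmann_eV_K: float = BOLTZMANN_EV_K
    T0_K: float = T0_K
    T0_star_K: float = T0_STAR_K

    def __post_init__(self) -> None:
        if self.boltzmann_eV_K <= 0:
            raise ValueError("Boltzmann constant must be positive")
        if self.T0_K <= 0 or self.T0_star_K <= 0:
            raise ValueError("reference temperatures must be positive (Kelvin)")


DEFAULT_CONSTANTS = PhysicalConstants()


def celsius_to_kelvin(t_celsius):
    """Convert degC to K (scalar or array)."""
    return np.asarray(t_celsius, dtype=float) + ZERO_CELSIUS_K


def kelvin_to_celsius(t_kelvin):
    """Convert K to degC (scalar or array)."""
    return np.asarray(t_kelvin, dtype=float) - ZERO_CELSIUS_K
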