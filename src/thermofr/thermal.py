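"""Boltzmann-Arrhenius temperature scaling of biological rates.

Every rate in the pipeline (attack coefficient, handling time, natural
mortality, metabolism) is modelled as a reference value at ``T0``
multiplied by the Arrhenius factor

    exp(E * (T - T0) / (k * T * T0))

with activation energy ``E`` in eV and the Boltzmann constant ``k`` in
eV/K.  Assimilation efficiency is a logistic transform of the same
factor, referenced to its own ``T0*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "ArrheniusRate",
    "AssimilationParams",
    "arrhenius_factor",
    "assimilation_efficiency",
]


def arrhenius_factor(activation_energy_eV, T_K, T0_K, boltzmann_eV_K=DEFAULT_CONSTANTS.boltzmann_eV_K):
    """Dimensionless Arrhenius multiplier taking a rate from ``T0`` to ``T``.

    Parameters
    ----------
    activation_energy_eV : float or array
        Activation energy in eV; zero gives a temperature-independent rate,
        negative values give rates that decline with warming.
    T_K, T0_K : float or array
        Absolute temperatures in Kelvin (both must be positive).
    boltzmann_eV_K : float
        Boltzmann constant in eV/K.

    Returns
    -------
    float or ndarray
        ``exp(E * (T - T0) / (k * T * T0))``; exactly 1 at ``T == T0``.
    """
    T = np.asarray(T_K, dtype=float)
    T0 = np.asarray(T0_K, dtype=float)
    if np.any(T <= 0) or np.any(T0 <= 0):
        raise ValueError("absolute temperatures must be positive (Kelvin)")
    exponent = np.asarray(activation_energy_eV, dtype=float) * (T - T0) / (boltzmann_eV_K * T * T0)
    out = np.exp(exponent)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ArrheniusRate:
    """A rate defined by its value at the reference temperature plus an
    activation energy.  Units of ``value_at_T0`` are the caller's."""

    value_at_T0: float
    activation_energy_eV: float = 0.0

    def __post_init__(self) -> None:
        if self.value_at_T0 < 0:
            raise ValueError("value_at_T0 must be non-negative")

    def at(self, T_K, consts: PhysicalConstants = DEFAULT_CONSTANTS):
        """Rate at absolute temperature ``T_K`` (scalar or array)."""
        return self.value_at_T0 * arrhenius_factor(
            self.activation_energy_eV, T_K, consts.T0_K, consts.boltzmann_eV_K
        )


@dataclass(frozen=True)
class AssimilationParams:
    """Parameters of the temperature-dependent assimilation efficiency.

    ``omega0`` is the intercept on the odds scale at ``T0_star_K``; the
    default ``e**2.266`` with activation energy 0.164 eV is the published
    meta-analytic relation for carnivorous invertebrates.
    """

    omega0: float = field(default_factory=lambda: float(np.exp(2.266)))
    E_omega_eV: float = 0.164
    T0_star_K: float = DEFAULT_CONSTANTS.T0_star_K

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.T0_star_K <= 0:
            raise ValueError("T0_star_K must be positive")


def assimilation_efficiency(T_K, params: AssimilationParams = AssimilationParams(),
                            boltzmann_eV_K=DEFAULT_CONSTANTS.boltzmann_eV_K):
    """Fraction of ingested energy assimilated, at temperature ``T_K``.

    Logistic transform of the Arrhenius-scaled odds, so the result is
    always strictly inside (0, 1) and increases with temperature whenever
    the activation energy is positive.
    """
    A = arrhenius_factor(params.E_omega_eV, T_K, params.T0_star_K, boltzmann_eV_K)
    odds = params.omega0 * A
    return odds / (1.0 + odds)
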