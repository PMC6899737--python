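"""Forward model of prey depletion in a feeding trial.

A single predator forages in a closed arena without prey replacement, so
the instantaneous functional response has to be integrated over the
declining prey density:

    dN/dt = -c(T) * N**h / (1 + c(T) * b(T) * N**h) - m(T) * N

with attack coefficient ``c``, handling time ``b`` (days/individual),
Hill exponent ``h`` (1 for type I/II, 2 for type III) and natural
mortality ``m``; each of ``c``, ``b``, ``m`` carries Boltzmann-Arrhenius
temperature dependence.  The type II, mortality-free case has a closed
form (the random-predator equation) used as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import lambertw

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .thermal import ArrheniusRate

__all__ = [
    "FRParams",
    "MortalityParams",
    "TrialConditions",
    "feeding_rate",
    "integrate_depletion",
    "depletion_endpoints",
    "rogers_closed_form",
]

FR_TYPES = ("I", "II", "III")

#: Default adaptive-solver tolerances; tight enough that the likelihood
#: surface stays smooth for quasi-Newton optimisation.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class FRParams:
    """Functional-response parameters for one predator in one setting.

    Type I is encoded as ``handling_time.value_at_T0 == 0`` (linear
    response, no saturation inside the depletion model); the Hill
    exponent is fixed at 1 for types I/II and 2 for type III, never a
    free parameter.
    """

    fr_type: str
    attack_coeff: ArrheniusRate
    handling_time: ArrheniusRate = ArrheniusRate(0.0, 0.0)

    def __post_init__(self) -> None:
        if self.fr_type not in FR_TYPES:
            raise ValueError(f"fr_type must be one of {FR_TYPES}, got {self.fr_type!r}")
        if self.attack_coeff.value_at_T0 <= 0:
            raise ValueError("attack coefficient must be positive")
        if self.handling_time.value_at_T0 < 0:
            raise ValueError("handling time must be non-negative")
        if self.fr_type == "I" and self.handling_time.value_at_T0 != 0:
            raise ValueError("type I requires zero handling time")
        if self.fr_type != "I" and self.handling_time.value_at_T0 == 0:
            raise ValueError(f"type {self.fr_type} requires positive handling time")

    @property
    def hill(self) -> int:
        return 2 if self.fr_type == "III" else 1


@dataclass(frozen=True)
class MortalityParams:
    """Background (predator-free) prey mortality rate, per day at T0."""

    m0: float = 0.0
    E_m_eV: float = 0.0

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")

    def rate(self) -> ArrheniusRate:
        return ArrheniusRate(self.m0, self.E_m_eV)


@dataclass(frozen=True)
class TrialConditions:
    """Initial conditions of one arena."""

    n0: int
    T_K: float
    duration_days: float = 1.0
    predator_present: bool = True

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("initial prey count must be non-negative")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.T_K <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


def feeding_rate(N, params: FRParams, T_K, consts: PhysicalConstants = DEFAULT_CONSTANTS):
    """Per capita feeding rate (prey individuals/day) at prey density ``N``.

    ``F = a N / (1 + a b N)`` with attack rate ``a = c(T) * N**(h-1)``;
    zero at zero density, saturating at ``1/b`` for positive handling
    time.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("prey density must be non-negative")
    c = params.attack_coeff.at(T_K, consts)
    b = params.handling_time.at(T_K, consts)
    a = c * np.where(N > 0, N, 1.0) ** (params.hill - 1)
    F = a * N / (1.0 + a * b * N)
    if F.ndim == 0:
        return float(F)
    return F


def _depletion_rhs(t, N, c, b, m, hill):
    Np = np.maximum(N, 0.0)
    Nh = Np ** hill
    return -c * Nh / (1.0 + c * b * Nh) - m * Np


def depletion_endpoints(n0, c, b, m, hill, duration_days,
                        rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
    """Expected prey remaining after ``duration_days`` for a batch of arenas.

    All arguments are broadcastable arrays; each arena depletes
    independently, so the whole batch is integrated as one vector ODE
    with a single adaptive Runge-Kutta call.  Results are clipped to
    ``[0, n0]`` (a warning is raised if the solver undershoots zero by
    more than the absolute tolerance).
    """
    n0, c, b, m, hill = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (n0, c, b, m, hill))
    )
    y0 = n0.ravel().astype(float)
    if y0.size == 0:
        return np.empty(0)
    sol = solve_ivp(
        _depletion_rhs,
        (0.0, float(duration_days)),
        y0,
        args=(c.ravel(), b.ravel(), m.ravel(), hill.ravel()),
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver failure is pathological here
        raise RuntimeError(f"depletion ODE solver failed: {sol.message}")
    out = sol.y[:, -1]
    if np.any(out < -1e-6):
        warnings.warn("depletion solver undershot zero prey; clipping", RuntimeWarning)
    return np.clip(out, 0.0, y0).reshape(n0.shape)


def integrate_depletion(cond: TrialConditions, fr: FRParams | None,
                        mort: MortalityParams = MortalityParams(),
                        consts: PhysicalConstants = DEFAULT_CONSTANTS,
                        rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> float:
    """Expected prey remaining at the end of one trial.

    With the predator absent only natural mortality acts and the decline
    is exactly exponential, so the closed form is returned; with the
    predator present the depletion ODE is integrated numerically to the
    trial endpoint.
    """
    if cond.n0 == 0:
        return 0.0
    m = mort.rate().at(cond.T_K, consts)
    if not cond.predator_present or fr is None:
        return float(cond.n0 * np.exp(-m * cond.duration_days))
    c = fr.attack_coeff.at(cond.T_K, consts)
    b = fr.handling_time.at(cond.T_K, consts)
    out = depletion_endpoints(cond.n0, c, b, m, fr.hill, cond.duration_days,
                              rtol=rtol, atol=atol)
    return float(out)


def rogers_closed_form(n0, a, b, t) -> float:
    """Prey eaten under a type II response with depletion and no mortality.

    Closed-form solution of the implicit random-predator equation
    ``N_e = N0 * (1 - exp(a * (b * N_e - t)))`` via the principal branch
    of the Lambert W function.  Serves as the independent oracle for the
    numerically integrated depletion model.
    """
    if a <= 0:
        raise ValueError("attack rate must be positive")
    if b < 0 or t < 0:
        raise ValueError("handling time and duration must be non-negative")
    n0 = float(n0)
    if n0 == 0 or t == 0:
        return 0.0
    if b == 0:
        return n0 * (1.0 - np.exp(-a * t))
    arg = a * b * n0 * np.exp(a * b * n0 - a * t)
    w = lambertw(arg, 0)
    if abs(w.imag) > 1e-12:  # pragma: no cover
        raise ArithmeticError("Lambert W returned a complex value")
    remaining = w.real / (a * b)
    return float(np.clip(n0 - remaining, 0.0, n0))
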