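"""Metabolic-rate scaling from respirometry.

Oxygen consumption rates are converted to J/h and regressed (OLS on the
natural-log scale) against body mass and the Arrhenius temperature
abscissa

    x = (T - T0) / (k * T * T0)

so that temperature coefficients are activation energies in eV.  The
candidate set crosses mass in/out, a mass-by-temperature interaction and
a quadratic temperature term; candidates are ranked by BIC.  A negative
quadratic coefficient implies an interior thermal optimum, recovered in
closed form from the vertex of the parabola in x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (DEFAULT_CONSTANTS, PhysicalConstants, celsius_to_kelvin,
                        kelvin_to_celsius)

__all__ = [
    "O2_JOULES_PER_UMOL",
    "MetabolicFit",
    "o2_to_joules",
    "arrhenius_abscissa",
    "fit_metabolic_models",
    "thermal_optimum",
    "predict_metabolic_rate",
]

# 1 umol O2 -> ug via molar mass 31.9988 g/mol, -> ul via density
# 1.429 g/L, -> J via 20.1 J/ml: 31.9988 / 1.429 * 20.1 / 1000 J/umol.
O2_MOLAR_MASS_G = 31.9988
O2_DENSITY_G_PER_L = 1.429
O2_JOULES_PER_ML = 20.1
O2_JOULES_PER_UMOL = O2_MOLAR_MASS_G / O2_DENSITY_G_PER_L * O2_JOULES_PER_ML / 1000.0


def o2_to_joules(o2_umol_per_h):
    """Convert an oxygen consumption rate (umol O2/h) to J/h."""
    rate = np.asarray(o2_umol_per_h, dtype=float)
    if np.any(rate < 0):
        raise ValueError("oxygen consumption rate must be non-negative")
    out = rate * O2_JOULES_PER_UMOL
    return float(out) if out.ndim == 0 else out


def arrhenius_abscissa(T_K, consts: PhysicalConstants = DEFAULT_CONSTANTS):
    """Temperature abscissa ``x = (T - T0)/(k T T0)`` (1/eV)."""
    T = np.asarray(T_K, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    x = (T - consts.T0_K) / (consts.boltzmann_eV_K * T * consts.T0_K)
    return float(x) if x.ndim == 0 else x


#: term name -> column builder; "x" is the Arrhenius abscissa, "ln_mass"
#: the log dry mass (mg).
_TERMS = ("intercept", "x", "x2", "ln_mass", "x_ln_mass")


def _candidate_term_sets(include_mass: bool):
    """Full crossing of temperature (none / linear / linear+quadratic),
    mass (in/out) and the mass-by-temperature interaction."""
    temp_options = [(), ("x",), ("x", "x2")]
    mass_options = [(), ("ln_mass",)] if include_mass else [()]
    out = []
    for temp in temp_options:
        for mass in mass_options:
            terms = ("intercept",) + temp + mass
            out.append(terms)
            if "x" in temp and mass:
                out.append(terms + ("x_ln_mass",))
    return out


@dataclass
class MetabolicFit:
    """One OLS candidate for ln(metabolic rate in J/h)."""

    terms: tuple
    coef: dict            # term -> estimate
    se: dict
    tvalues: dict
    pvalues: dict
    r2: float
    loglik: float
    n: int
    bic: float
    consts: PhysicalConstants = DEFAULT_CONSTANTS
    selected: bool = False

    @property
    def k(self) -> int:
        return len(self.terms)

    @property
    def uses_mass(self) -> bool:
        return "ln_mass" in self.terms or "x_ln_mass" in self.terms

    def describe(self) -> str:
        return "ln I ~ " + " + ".join(t for t in self.terms)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "estimate": self.coef[t], "se": self.se[t],
                 "t": self.tvalues[t], "p": self.pvalues[t]} for t in self.terms]
        df = pd.DataFrame(rows)
        df["model"] = self.describe()
        df["r2"] = self.r2
        df["n"] = self.n
        df["BIC"] = self.bic
        df["selected"] = self.selected
        return df


def _design_matrix(terms, x, ln_mass):
    cols = {"intercept": np.ones_like(x), "x": x, "x2": x ** 2}
    if ln_mass is not None:
        cols["ln_mass"] = ln_mass
        cols["x_ln_mass"] = x * ln_mass
    return np.column_stack([cols[t] for t in terms])


def fit_metabolic_models(records: pd.DataFrame,
                         consts: PhysicalConstants = DEFAULT_CONSTANTS) -> list[MetabolicFit]:
    """Fit and BIC-rank the candidate metabolic regressions.

    ``records`` needs columns ``temperature_C`` and ``o2_umol_per_h``
    (or a precomputed ``metabolic_rate_J_h``); ``dry_mass_mg`` is
    optional — if absent or constant, mass-containing candidates are
    dropped with a warning.  Returns fits sorted ascending by BIC with
    the winner flagged.
    """
    if "temperature_C" not in records.columns:
        raise ValueError("records require a temperature_C column")
    if "metabolic_rate_J_h" in records.columns:
        rate = records["metabolic_rate_J_h"].to_numpy(dtype=float)
    elif "o2_umol_per_h" in records.columns:
        rate = o2_to_joules(records["o2_umol_per_h"].to_numpy(dtype=float))
    else:
        raise ValueError("records require o2_umol_per_h or metabolic_rate_J_h")
    if np.any(rate <= 0):
        raise ValueError("metabolic rates must be positive to fit on the log scale")
    if len(records) < 3 or records["temperature_C"].nunique() < 2:
        raise ValueError("need at least 3 records spanning at least 2 temperatures")

    T_K = celsius_to_kelvin(records["temperature_C"].to_numpy())
    x = arrhenius_abscissa(T_K, consts)
    y = np.log(rate)

    ln_mass = None
    if "dry_mass_mg" in records.columns and records["dry_mass_mg"].notna().all():
        mass = records["dry_mass_mg"].to_numpy(dtype=float)
        if np.ptp(mass) > 0:
            ln_mass = np.log(mass)
        else:
            warnings.warn("dry mass is constant; mass terms excluded", RuntimeWarning)

    fits = []
    for terms in _candidate_term_sets(include_mass=ln_mass is not None):
        X = _design_matrix(terms, x, ln_mass)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"singular design for terms {terms}; candidate dropped",
                          RuntimeWarning)
            continue
        res = sm.OLS(y, X).fit()
        fits.append(MetabolicFit(
            terms=terms,
            coef={t: float(res.params[i]) for i, t in enumerate(terms)},
            se={t: float(res.bse[i]) for i, t in enumerate(terms)},
            tvalues={t: float(res.tvalues[i]) for i, t in enumerate(terms)},
            pvalues={t: float(res.pvalues[i]) for i, t in enumerate(terms)},
            r2=float(res.rsquared), loglik=float(res.llf), n=int(res.nobs),
            bic=float(res.bic), consts=consts))
    fits.sort(key=lambda f: (f.bic, f.k))
    if fits:
        fits[0].selected = True
    return fits


def predict_metabolic_rate(fit: MetabolicFit, T_K, dry_mass_mg=None):
    """Predicted metabolic rate (J/h) at temperature ``T_K`` and, if the
    model includes mass terms, dry mass in mg."""
    x = arrhenius_abscissa(T_K, fit.consts)
    if fit.uses_mass:
        if dry_mass_mg is None:
            raise ValueError("this metabolic model requires a body mass")
        ln_mass = np.log(np.asarray(dry_mass_mg, dtype=float))
    else:
        ln_mass = None
    lp = np.zeros_like(np.asarray(x, dtype=float))
    for t in fit.terms:
        if t == "intercept":
            lp = lp + fit.coef[t]
        elif t == "x":
            lp = lp + fit.coef[t] * x
        elif t == "x2":
            lp = lp + fit.coef[t] * np.asarray(x) ** 2
        elif t == "ln_mass":
            lp = lp + fit.coef[t] * ln_mass
        elif t == "x_ln_mass":
            lp = lp + fit.coef[t] * np.asarray(x) * ln_mass
    out = np.exp(lp)
    return float(out) if np.ndim(out) == 0 else out


def thermal_optimum(fit: MetabolicFit) -> float | None:
    """Temperature (K) maximising the predicted rate, or None.

    Requires a quadratic temperature term with a negative coefficient;
    the vertex in the Arrhenius abscissa, ``x* = -E / (2 q)``, maps back
    to temperature via ``T* = T0 / (1 - x* k T0)``.
    """
    if "x2" not in fit.terms:
        raise ValueError("thermal_optimum requires a quadratic temperature term")
    q = fit.coef["x2"]
    if q >= 0:
        return None
    E = fit.coef.get("x", 0.0)
    x_star = -E / (2.0 * q)
    consts = fit.consts
    denom = 1.0 - x_star * consts.boltzmann_eV_K * consts.T0_K
    if denom <= 0:  # optimum beyond the physical temperature range
        return None
    return float(consts.T0_K / denom)


def thermal_optimum_celsius(fit: MetabolicFit) -> float | None:
    t = thermal_optimum(fit)
    return None if t is None else float(kelvin_to_celsius(t))
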