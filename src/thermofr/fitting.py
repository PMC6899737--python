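"""Maximum-likelihood fitting of depletion functional responses.

Feeding trials record how many of ``n0`` prey survive 24 h in an arena.
The eaten count in each arena is modelled as Binomial(n0, p_eaten) where
``p_eaten`` is the eaten fraction predicted by the depletion ODE under
the candidate parameters, following the standard likelihood for
prey-depletion designs.  Natural mortality is estimated first from the
predator-free controls and frozen into the depletion model (two-stage
plug-in).  Parameter sharing across experimental settings (separate or
shared intercepts, and zero/shared/separate activation energies) spans a
zoo of 55 candidate models per predator, ranked by BIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .depletion import (DEFAULT_ATOL, DEFAULT_RTOL, FRParams, MortalityParams,
                        depletion_endpoints)
from .thermal import ArrheniusRate, arrhenius_factor

__all__ = [
    "ShareStructure",
    "STRUCTURES",
    "FRModelSpec",
    "FRFit",
    "MortalityCandidate",
    "MortalityFit",
    "ModelSelection",
    "trial_neg_log_likelihood",
    "fit_mortality",
    "enumerate_model_zoo",
    "fit_fr_model",
    "select_by_bic",
]

#: Probability clip guarding the binomial log-likelihood.
P_EPS = 1e-12

_LOG_BOUNDS = (-12.0, 7.0)   # bounds for log-scale rate parameters
_E_BOUNDS = (-3.0, 4.0)      # bounds for activation energies (eV)


# ---------------------------------------------------------------------------
# model structures


@dataclass(frozen=True, order=True)
class ShareStructure:
    """How one parameter family (intercept + activation energy) is shared
    across datasets.

    ``intercepts`` is ``"shared"`` or ``"separate"``; ``energies`` is
    ``"zero"`` (no temperature dependence), ``"shared"`` or
    ``"separate"``.  Separate activation energies require separate
    intercepts, which leaves five admissible structures per family.
    """

    intercepts: str
    energies: str

    def __post_init__(self) -> None:
        if self.intercepts not in ("shared", "separate"):
            raise ValueError("intercepts must be 'shared' or 'separate'")
        if self.energies not in ("zero", "shared", "separate"):
            raise ValueError("energies must be 'zero', 'shared' or 'separate'")
        if self.energies == "separate" and self.intercepts == "shared":
            raise ValueError("separate activation energies require separate intercepts")

    def n_free(self, n_datasets: int) -> int:
        n_int = 1 if self.intercepts == "shared" else n_datasets
        n_e = {"zero": 0, "shared": 1, "separate": n_datasets}[self.energies]
        return n_int + n_e

    def label(self) -> str:
        return f"{self.intercepts}-c0/{self.energies}-E"


STRUCTURES: tuple[ShareStructure, ...] = (
    ShareStructure("shared", "zero"),
    ShareStructure("shared", "shared"),
    ShareStructure("separate", "zero"),
    ShareStructure("separate", "shared"),
    ShareStructure("separate", "separate"),
)


@dataclass(frozen=True)
class FRModelSpec:
    """One candidate model: response type plus sharing structure for the
    attack coefficient and (for types II/III) the handling time."""

    fr_type: str
    c_structure: ShareStructure
    b_structure: ShareStructure | None = None

    def __post_init__(self) -> None:
        if self.fr_type not in ("I", "II", "III"):
            raise ValueError("fr_type must be I, II or III")
        if self.fr_type == "I" and self.b_structure is not None:
            raise ValueError("type I has no handling time structure")
        if self.fr_type != "I" and self.b_structure is None:
            raise ValueError(f"type {self.fr_type} requires a handling-time structure")

    @property
    def hill(self) -> int:
        return 2 if self.fr_type == "III" else 1

    def n_free(self, n_datasets: int) -> int:
        k = self.c_structure.n_free(n_datasets)
        if self.b_structure is not None:
            k += self.b_structure.n_free(n_datasets)
        return k

    def describe(self) -> str:
        s = f"type {self.fr_type}, attack {self.c_structure.label()}"
        if self.b_structure is not None:
            s += f", handling {self.b_structure.label()}"
        return s

    def sort_key(self):
        return (self.fr_type, STRUCTURES.index(self.c_structure),
                -1 if self.b_structure is None else STRUCTURES.index(self.b_structure))


def enumerate_model_zoo(n_datasets: int = 3) -> list[FRModelSpec]:
    """All candidate functional-response models for one predator.

    Types II and III cross the five attack-coefficient structures with
    the five handling-time structures; type I (no handling time) adds
    its five attack structures, for 55 models in total regardless of the
    number of datasets.
    """
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    zoo = [FRModelSpec("I", c) for c in STRUCTURES]
    for fr_type, c, b in itertools.product(("II", "III"), STRUCTURES, STRUCTURES):
        zoo.append(FRModelSpec(fr_type, c, b))
    return zoo


# ---------------------------------------------------------------------------
# trial data validation and likelihood


def _validate_trials(trials: pd.DataFrame, require_predator: bool | None = None) -> pd.DataFrame:
    required = {"dataset_id", "temperature_C", "n0", "n_survivors"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials frame missing columns: {sorted(missing)}")
    t = trials.copy()
    if "duration_days" not in t.columns:
        t["duration_days"] = 1.0
    if "predator_present" not in t.columns:
        t["predator_present"] = True
    bad = t.index[(t["n_survivors"] < 0) | (t["n_survivors"] > t["n0"]) | (t["n0"] < 0)]
    if len(bad):
        raise ValueError(f"invalid counts (survivors outside [0, n0]) in rows {list(bad[:5])}")
    if require_predator is not None:
        t = t[t["predator_present"] == require_predator]
    return t


class _TrialLikelihood:
    """Precomputed binomial depletion likelihood for a fixed set of trials.

    Arenas sharing (dataset, temperature, n0, duration) share one ODE
    solution, so the trials are grouped into unique cells once and every
    likelihood evaluation integrates the whole batch in a single
    vectorised solver call.
    """

    def __init__(self, trials: pd.DataFrame, consts: PhysicalConstants = DEFAULT_CONSTANTS,
                 rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
        from .constants import celsius_to_kelvin

        t = _validate_trials(trials, require_predator=True)
        if t.empty:
            raise ValueError("no predator-present trials to fit")
        if t["n0"].min() < 1:
            raise ValueError("predator trials require n0 >= 1")
        durations = t["duration_days"].unique()
        if len(durations) != 1:
            raise ValueError("mixed trial durations are not supported in one fit")
        self.duration = float(durations[0])
        self.consts = consts
        self.rtol, self.atol = rtol, atol
        self.datasets = tuple(sorted(t["dataset_id"].unique()))

        cells = (t[["dataset_id", "temperature_C", "n0"]]
                 .drop_duplicates().reset_index(drop=True))
        self.cell_dataset_idx = np.array([self.datasets.index(d) for d in cells["dataset_id"]])
        self.cell_T_K = celsius_to_kelvin(cells["temperature_C"].to_numpy())
        self.cell_n0 = cells["n0"].to_numpy(dtype=float)

        key = cells["dataset_id"].astype(str) + "|" + cells["temperature_C"].astype(str) \
            + "|" + cells["n0"].astype(str)
        lookup = {k: i for i, k in enumerate(key)}
        tkey = t["dataset_id"].astype(str) + "|" + t["temperature_C"].astype(str) \
            + "|" + t["n0"].astype(str)
        self.trial_cell = np.array([lookup[k] for k in tkey])
        self.trial_n0 = t["n0"].to_numpy(dtype=float)
        self.trial_eaten = self.trial_n0 - t["n_survivors"].to_numpy(dtype=float)
        # binomial coefficient is parameter-free
        self.log_binom = (gammaln(self.trial_n0 + 1)
                          - gammaln(self.trial_eaten + 1)
                          - gammaln(self.trial_n0 - self.trial_eaten + 1))
        self.n_obs = len(t)

    def _cell_rates(self, per_dataset: dict, attr: str) -> np.ndarray:
        vals = np.empty(len(self.cell_n0))
        for i, ds in enumerate(self.datasets):
            mask = self.cell_dataset_idx == i
            rate: ArrheniusRate = getattr(per_dataset[ds], attr)
            vals[mask] = rate.at(self.cell_T_K[mask], self.consts)
        return vals

    def p_eaten(self, fr_by_dataset: dict, mort_by_dataset: dict) -> np.ndarray:
        c = self._cell_rates(fr_by_dataset, "attack_coeff")
        b = self._cell_rates(fr_by_dataset, "handling_time")
        hill = np.array([fr_by_dataset[self.datasets[i]].hill for i in self.cell_dataset_idx],
                        dtype=float)
        m = np.empty(len(self.cell_n0))
        for i, ds in enumerate(self.datasets):
            mask = self.cell_dataset_idx == i
            m[mask] = mort_by_dataset[ds].rate().at(self.cell_T_K[mask], self.consts)
        remaining = depletion_endpoints(self.cell_n0, c, b, m, hill, self.duration,
                                        rtol=self.rtol, atol=self.atol)
        p = (self.cell_n0 - remaining) / self.cell_n0
        return np.clip(p, P_EPS, 1.0 - P_EPS)

    def nll(self, fr_by_dataset: dict, mort_by_dataset: dict) -> float:
        p = self.p_eaten(fr_by_dataset, mort_by_dataset)[self.trial_cell]
        ll = (self.log_binom + self.trial_eaten * np.log(p)
              + (self.trial_n0 - self.trial_eaten) * np.log1p(-p))
        total = ll.sum()
        if not np.isfinite(total):
            raise ArithmeticError("non-finite trial likelihood")
        return float(-total)


def trial_neg_log_likelihood(trials: pd.DataFrame, fr_by_dataset: dict,
                             mort_by_dataset: dict,
                             consts: PhysicalConstants = DEFAULT_CONSTANTS,
                             rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> float:
    """Total negative log-likelihood of predator-present feeding trials.

    Each arena contributes ``-log Binomial(eaten; n0, p_eaten)`` with
    ``p_eaten`` the ODE-predicted eaten fraction, clipped away from 0/1.
    ``fr_by_dataset`` and ``mort_by_dataset`` map dataset labels to
    :class:`FRParams` / :class:`MortalityParams`.
    """
    lik = _TrialLikelihood(trials, consts=consts, rtol=rtol, atol=atol)
    missing = [d for d in lik.datasets if d not in fr_by_dataset or d not in mort_by_dataset]
    if missing:
        raise ValueError(f"missing parameters for datasets {missing}")
    return lik.nll(fr_by_dataset, mort_by_dataset)


# ---------------------------------------------------------------------------
# mortality from predator-free controls


@dataclass(frozen=True)
class MortalityCandidate:
    model: str                      # "zero", "constant" or "arrhenius"
    params: MortalityParams
    loglik: float
    k: int
    n: int
    bic: float
    se: tuple | None = None         # SEs on (log m0, E_m) where estimated


@dataclass
class MortalityFit:
    """Per-dataset mortality candidates with the BIC winner selected."""

    candidates: dict = field(default_factory=dict)   # dataset -> list[MortalityCandidate]
    selected: dict = field(default_factory=dict)     # dataset -> MortalityCandidate

    def params_for(self, dataset: str) -> MortalityParams:
        return self.selected[dataset].params

    def as_params_dict(self) -> dict:
        return {d: c.params for d, c in self.selected.items()}

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for ds, cands in self.candidates.items():
            for c in cands:
                rows.append({"dataset_id": ds, "model": c.model, "m0": c.params.m0,
                             "E_m_eV": c.params.E_m_eV, "logLik": c.loglik, "k": c.k,
                             "n": c.n, "BIC": c.bic,
                             "selected": c is self.selected[ds]})
        return pd.DataFrame(rows)


def _mortality_nll(m0, E_m, T_K, n0, deaths, duration, consts):
    m = m0 * arrhenius_factor(E_m, T_K, consts.T0_K, consts.boltzmann_eV_K)
    p_die = np.clip(1.0 - np.exp(-m * duration), P_EPS, 1.0 - P_EPS)
    log_binom = gammaln(n0 + 1) - gammaln(deaths + 1) - gammaln(n0 - deaths + 1)
    ll = log_binom + deaths * np.log(p_die) + (n0 - deaths) * np.log1p(-p_die)
    return float(-ll.sum())


def fit_mortality(controls: pd.DataFrame, consts: PhysicalConstants = DEFAULT_CONSTANTS,
                  seed: int = 0) -> MortalityFit:
    """Fit background prey mortality from predator-free control arenas.

    For every dataset three nested candidates are compared by BIC:
    no mortality (``m0 = 0``), a temperature-independent rate, and an
    Arrhenius temperature-dependent rate.  The winning point estimates
    are frozen for plug-in use by the functional-response stage.
    """
    from .constants import celsius_to_kelvin

    t = _validate_trials(controls, require_predator=False)
    if "excluded" in t.columns:
        t = t[~t["excluded"].astype(bool)]
    if t.empty:
        raise ValueError("no control trials supplied")

    fit = MortalityFit()
    for ds, grp in t.groupby("dataset_id"):
        T_K = celsius_to_kelvin(grp["temperature_C"].to_numpy())
        n0 = grp["n0"].to_numpy(dtype=float)
        deaths = n0 - grp["n_survivors"].to_numpy(dtype=float)
        duration = grp["duration_days"].to_numpy(dtype=float)
        n = len(grp)
        cands = []

        ll0 = -_mortality_nll(0.0, 0.0, T_K, n0, deaths, duration, consts)
        cands.append(MortalityCandidate("zero", MortalityParams(0.0, 0.0), ll0, 0, n,
                                        -2.0 * ll0))
        if deaths.sum() > 0:
            res1 = minimize_scalar(
                lambda lm: _mortality_nll(np.exp(lm), 0.0, T_K, n0, deaths, duration, consts),
                bounds=_LOG_BOUNDS, method="bounded",
                options={"xatol": 1e-10})
            m0_hat = float(np.exp(res1.x))
            ll1 = -res1.fun
            se1 = _wald_se(lambda th: _mortality_nll(np.exp(th[0]), 0.0, T_K, n0, deaths,
                                                     duration, consts), np.array([res1.x]))
            cands.append(MortalityCandidate("constant", MortalityParams(m0_hat, 0.0),
                                            ll1, 1, n, 1 * np.log(n) - 2.0 * ll1,
                                            se=tuple(se1) if se1 is not None else None))

            rng = np.random.default_rng(seed)
            best = None
            starts = [np.array([res1.x, 0.6])] + [
                np.array([rng.uniform(np.log(1e-3), np.log(1.0)), rng.uniform(-1, 2)])
                for _ in range(4)]
            for x0 in starts:
                r = minimize(
                    lambda th: _mortality_nll(np.exp(th[0]), th[1], T_K, n0, deaths,
                                              duration, consts),
                    x0, method="L-BFGS-B",
                    bounds=[_LOG_BOUNDS, _E_BOUNDS])
                if r.success and (best is None or r.fun < best.fun):
                    best = r
            if best is not None:
                ll2 = -best.fun
                se2 = _wald_se(lambda th: _mortality_nll(np.exp(th[0]), th[1], T_K, n0,
                                                         deaths, duration, consts), best.x)
                cands.append(MortalityCandidate(
                    "arrhenius", MortalityParams(float(np.exp(best.x[0])), float(best.x[1])),
                    ll2, 2, n, 2 * np.log(n) - 2.0 * ll2,
                    se=tuple(se2) if se2 is not None else None))

        cands.sort(key=lambda c: (c.bic, c.k))
        fit.candidates[ds] = cands
        fit.selected[ds] = cands[0]
    return fit


# ---------------------------------------------------------------------------
# numerical Wald machinery


def _numerical_hessian(fun, x, rel_step=5e-3):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _wald_se(fun, x):
    """Standard errors from the inverse Hessian of a negative log-likelihood;
    None if the Hessian is not positive-definite."""
    try:
        H = _numerical_hessian(fun, np.asarray(x, dtype=float))
        eigs = np.linalg.eigvalsh(H)
        if np.any(eigs <= 0):
            return None
        cov = np.linalg.inv(H)
        return np.sqrt(np.diag(cov))
    except (np.linalg.LinAlgError, ArithmeticError):
        return None


# ---------------------------------------------------------------------------
# functional-response model fitting


def _param_layout(spec: FRModelSpec, datasets: tuple):
    """Names and scales of the free parameters of ``spec``.

    Rate intercepts (c0, b0) are fitted on the natural-log scale so that
    positivity is automatic and Wald z-values follow the
    ``ln(estimate)/SE`` convention; activation energies are linear.
    Returns (names, scales, unpack) where unpack maps a parameter vector
    to per-dataset :class:`FRParams`.
    """
    names, scales, getters = [], [], {}

    def add_family(prefix, structure):
        fam = {}
        if structure is None:
            for ds in datasets:
                fam[ds] = (None, None)
            return fam
        if structure.intercepts == "shared":
            idx = len(names)
            names.append(f"{prefix}0"); scales.append("log")
            int_idx = {ds: idx for ds in datasets}
        else:
            int_idx = {}
            for ds in datasets:
                int_idx[ds] = len(names)
                names.append(f"{prefix}0[{ds}]"); scales.append("log")
        if structure.energies == "zero":
            e_idx = {ds: None for ds in datasets}
        elif structure.energies == "shared":
            idx = len(names)
            names.append(f"E_{prefix}"); scales.append("linear")
            e_idx = {ds: idx for ds in datasets}
        else:
            e_idx = {}
            for ds in datasets:
                e_idx[ds] = len(names)
                names.append(f"E_{prefix}[{ds}]"); scales.append("linear")
        for ds in datasets:
            fam[ds] = (int_idx[ds], e_idx[ds])
        return fam

    getters["c"] = add_family("c", spec.c_structure)
    getters["b"] = add_family("b", spec.b_structure)

    def unpack(theta):
        out = {}
        for ds in datasets:
            ci, cei = getters["c"][ds]
            c0 = float(np.exp(theta[ci]))
            E_c = 0.0 if cei is None else float(theta[cei])
            bi, bei = getters["b"][ds]
            if bi is None:
                b0, E_b = 0.0, 0.0
            else:
                b0 = float(np.exp(theta[bi]))
                E_b = 0.0 if bei is None else float(theta[bei])
            out[ds] = FRParams(spec.fr_type, ArrheniusRate(c0, E_c),
                               ArrheniusRate(b0, E_b))
        return out

    return tuple(names), tuple(scales), unpack


@dataclass
class FRFit:
    """A fitted functional-response model with Wald summaries."""

    spec: FRModelSpec
    datasets: tuple
    param_names: tuple
    param_scales: tuple
    theta: np.ndarray               # estimates on the fitting scale
    se: np.ndarray | None           # SEs on the fitting scale (None if Hessian failed)
    loglik: float
    n_obs: int
    bic: float
    converged: bool
    n_starts_converged: int = 0
    _unpack: object = None

    @property
    def k(self) -> int:
        return len(self.param_names)

    def estimates_natural(self) -> dict:
        out = {}
        for name, scale, th in zip(self.param_names, self.param_scales, self.theta):
            out[name] = float(np.exp(th)) if scale == "log" else float(th)
        return out

    def params_by_dataset(self) -> dict:
        return self._unpack(self.theta)

    def params_for(self, dataset: str) -> FRParams:
        return self.params_by_dataset()[dataset]

    def summary_frame(self) -> pd.DataFrame:
        nat = self.estimates_natural()
        rows = []
        for i, (name, scale) in enumerate(zip(self.param_names, self.param_scales)):
            se = np.nan if self.se is None else float(self.se[i])
            z = float(self.theta[i]) / se if se and np.isfinite(se) else np.nan
            p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
            base = name.split("[")[0]
            ds = name[name.find("[") + 1:-1] if "[" in name else "combined"
            rows.append({"model": self.spec.describe(), "parameter": base,
                         "dataset": ds, "estimate": nat[name],
                         "estimate_fitscale": float(self.theta[i]),
                         "scale": scale, "se": se, "z": z, "p": p})
        df = pd.DataFrame(rows)
        df["logLik"] = self.loglik
        df["k"] = self.k
        df["n"] = self.n_obs
        df["BIC"] = self.bic
        return df


def fit_fr_model(spec: FRModelSpec, trials: pd.DataFrame, mort,
                 consts: PhysicalConstants = DEFAULT_CONSTANTS,
                 n_starts: int = 10, seed: int = 0,
                 rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                 compute_se: bool = True) -> FRFit:
    """Maximum-likelihood fit of one candidate model to feeding trials.

    ``mort`` is a :class:`MortalityFit` or a dataset->MortalityParams
    mapping, frozen during optimisation.  A bounded L-BFGS-B search is
    run from ``n_starts`` points (one central heuristic plus seeded
    random draws: rate intercepts log-uniform on [1e-3, 1e2], energies
    uniform on [-1, 2]); standard errors come from the inverse of a
    finite-difference Hessian at the optimum.
    """
    t = _validate_trials(trials, require_predator=True)
    if "excluded" in t.columns:
        t = t[~t["excluded"].astype(bool)]
    lik = _TrialLikelihood(t, consts=consts, rtol=rtol, atol=atol)
    datasets = lik.datasets
    mort_by_ds = mort.as_params_dict() if isinstance(mort, MortalityFit) else dict(mort)
    missing = [d for d in datasets if d not in mort_by_ds]
    if missing:
        raise ValueError(f"no mortality estimates for datasets {missing}")

    names, scales, unpack = _param_layout(spec, datasets)
    k = len(names)

    def objective(theta):
        try:
            return lik.nll(unpack(theta), mort_by_ds)
        except ArithmeticError:
            return 1e12

    rng = np.random.default_rng(seed)
    central = np.array([0.0 if s == "log" else 0.6 for s in scales])
    starts = [central]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([
            rng.uniform(np.log(1e-3), np.log(1e2)) if s == "log" else rng.uniform(-1.0, 2.0)
            for s in scales]))
    bounds = [_LOG_BOUNDS if s == "log" else _E_BOUNDS for s in scales]

    # The objective is evaluated through an adaptive ODE solver, so it
    # carries ~rtol relative noise; the finite-difference step for the
    # quasi-Newton gradient must sit well above that noise floor.
    fd_eps = max(1e-4, 100.0 * rtol)
    best, n_ok = None, 0
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"eps": fd_eps, "maxiter": 500})
        if res.success:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        warnings.warn(f"fit failed to converge for {spec.describe()}", RuntimeWarning)
        return FRFit(spec, datasets, names, scales,
                     np.full(k, np.nan), None, -np.inf, lik.n_obs, np.inf,
                     converged=False, n_starts_converged=0, _unpack=unpack)

    loglik = -float(best.fun)
    bic = k * np.log(lik.n_obs) - 2.0 * loglik
    se = _wald_se(objective, best.x) if compute_se else None
    if compute_se and se is None:
        warnings.warn(f"Hessian not positive-definite for {spec.describe()}; "
                      "standard errors unavailable", RuntimeWarning)
    return FRFit(spec, datasets, names, scales, best.x.copy(), se,
                 loglik, lik.n_obs, float(bic), converged=True,
                 n_starts_converged=n_ok, _unpack=unpack)


# ---------------------------------------------------------------------------
# BIC model selection


@dataclass
class ModelSelection:
    ranked: list
    winner: FRFit

    def table(self) -> pd.DataFrame:
        rows = []
        for rank, f in enumerate(self.ranked, start=1):
            rows.append({"rank": rank, "model": f.spec.describe(), "k": f.k,
                         "n": f.n_obs, "logLik": f.loglik, "BIC": f.bic,
                         "winner": rank == 1})
        return pd.DataFrame(rows)


def select_by_bic(fits) -> ModelSelection:
    """Rank successful fits ascending by BIC; the lowest BIC wins, ties
    broken by fewer free parameters then by model enumeration order."""
    ok = [f for f in fits if f.converged and np.isfinite(f.bic)]
    if not ok:
        raise ValueError("no successful fits to select from")
    ranked = sorted(ok, key=lambda f: (f.bic, f.k, f.spec.sort_key()))
    return ModelSelection(ranked=ranked, winner=ranked[0])
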