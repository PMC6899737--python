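import numpy as np
import pandas as pd
import pytest

from thermofr.constants import DEFAULT_CONSTANTS, celsius_to_kelvin
from thermofr.metabolism import (O2_JOULES_PER_UMOL, MetabolicFit,
                                 arrhenius_abscissa, fit_metabolic_models,
                                 o2_to_joules, predict_metabolic_rate,
                                 thermal_optimum, thermal_optimum_celsius)

TEMPS = (5.0, 10.0, 15.0, 20.0, 25.0)


def make_records(coef, n_per_temp=8, sigma=0.0, seed=0, masses=True):
    """Noise-free (or noisy) records lying on a given log-linear surface."""
    rng = np.random.default_rng(seed)
    rows = []
    for Tc in TEMPS:
        x = arrhenius_abscissa(float(celsius_to_kelvin(Tc)))
        m = np.exp(rng.uniform(np.log(0.5), np.log(5.0), n_per_temp))
        ln_rate = (coef.get("intercept", 0.0) + coef.get("x", 0.0) * x
                   + coef.get("x2", 0.0) * x ** 2
                   + coef.get("ln_mass", 0.0) * np.log(m)
                   + rng.normal(0, sigma, n_per_temp))
        for mi, ri in zip(m, np.exp(ln_rate)):
            rows.append(("sp", Tc, mi if masses else 1.0, ri / O2_JOULES_PER_UMOL))
    return pd.DataFrame(rows, columns=["species", "temperature_C", "dry_mass_mg",
                                       "o2_umol_per_h"])


class TestO2Conversion:
    def test_unit_rate_constant_from_printed_factors(self):
        # (31.9988 / 1.429) * 20.1 / 1000, evaluated independently
        assert o2_to_joules(1.0) == pytest.approx(0.4501, abs=1e-4)

    def test_zero_and_linearity(self):
        assert o2_to_joules(0.0) == 0.0
        assert o2_to_joules(10.0) == pytest.approx(10 * o2_to_joules(1.0), rel=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            o2_to_joules(-0.1)


class TestCandidateRegressions:
    def test_exact_recovery_of_mass_temperature_structure(self):
        coef = {"intercept": -4.171, "ln_mass": 0.525, "x": 0.687}
        fits = fit_metabolic_models(make_records(coef))
        winner = fits[0]
        assert winner.selected
        assert set(winner.terms) == {"intercept", "x", "ln_mass"}
        for term, val in coef.items():
            assert winner.coef[term] == pytest.approx(val, abs=1e-9)
        assert winner.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_recovery_of_quadratic_temperature_only_structure(self):
        coef = {"intercept": -1.056, "x": 1.072, "x2": -0.339}
        fits = fit_metabolic_models(make_records(coef))
        winner = fits[0]
        assert set(winner.terms) == {"intercept", "x", "x2"}
        for term, val in coef.items():
            assert winner.coef[term] == pytest.approx(val, abs=1e-9)

    def test_every_candidate_recovers_its_own_noise_free_surface(self):
        coef = {"intercept": -2.0, "x": 0.6, "x2": -0.2, "ln_mass": 0.7}
        fits = fit_metabolic_models(make_records(coef))
        full = [f for f in fits if set(f.terms) ==
                {"intercept", "x", "x2", "ln_mass"}][0]
        for term, val in coef.items():
            assert full.coef[term] == pytest.approx(val, abs=1e-8)

    def test_constant_mass_excludes_mass_candidates(self):
        coef = {"intercept": -1.0, "x": 0.5}
        with pytest.warns(RuntimeWarning):
            fits = fit_metabolic_models(make_records(coef, masses=False))
        assert all(not f.uses_mass for f in fits)

    def test_ranking_invariant_to_record_order(self):
        coef = {"intercept": -4.171, "ln_mass": 0.525, "x": 0.687}
        rec = make_records(coef, sigma=0.4, seed=3)
        a = fit_metabolic_models(rec)
        b = fit_metabolic_models(rec.sample(frac=1.0, random_state=7))
        assert [f.terms for f in a] == [f.terms for f in b]
        assert np.allclose([f.bic for f in a], [f.bic for f in b])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            fit_metabolic_models(make_records({"x": 0.5}).head(2))


class TestThermalOptimum:
    @staticmethod
    def quad_fit(E, q):
        return MetabolicFit(terms=("intercept", "x", "x2"),
                            coef={"intercept": -1.0, "x": E, "x2": q},
                            se={}, tvalues={}, pvalues={}, r2=0.5, loglik=0.0,
                            n=40, bic=0.0)

    def test_vertex_of_reported_quadratic_is_about_21_4_C(self):
        topt = thermal_optimum_celsius(self.quad_fit(1.072, -0.339))
        assert 21.3 <= topt <= 21.6

    def test_agrees_with_dense_grid_search(self):
        fit = self.quad_fit(1.072, -0.339)
        grid = np.linspace(274.0, 310.0, 720001)
        rates = predict_metabolic_rate(fit, grid)
        t_grid = grid[np.argmax(rates)]
        assert thermal_optimum(fit) == pytest.approx(t_grid, abs=0.01)

    def test_monotone_model_has_no_optimum(self):
        assert thermal_optimum(self.quad_fit(0.8, 0.05)) is None

    def test_scaling_both_coefficients_leaves_optimum_unchanged(self):
        a = thermal_optimum(self.quad_fit(1.072, -0.339))
        b = thermal_optimum(self.quad_fit(2.144, -0.678))
        assert a == pytest.approx(b, rel=1e-12)


class TestPrediction:
    def test_reference_point_returns_intercept(self):
        coef = {"intercept": -4.171, "ln_mass": 0.525, "x": 0.687}
        fits = fit_metabolic_models(make_records(coef))
        rate = predict_metabolic_rate(fits[0], DEFAULT_CONSTANTS.T0_K, 1.0)
        assert rate == pytest.approx(np.exp(-4.171), rel=1e-9)

    def test_mass_doubling_follows_power_law(self):
        coef = {"intercept": -4.171, "ln_mass": 0.525, "x": 0.687}
        winner = fit_metabolic_models(make_records(coef))[0]
        r1 = predict_metabolic_rate(winner, 290.0, 1.7)
        r2 = predict_metabolic_rate(winner, 290.0, 3.4)
        assert r2 / r1 == pytest.approx(2 ** 0.525, rel=1e-9)

    def test_mass_free_model_ignores_mass_and_requires_none(self):
        coef = {"intercept": -1.056, "x": 1.072, "x2": -0.339}
        winner = fit_metabolic_models(make_records(coef))[0]
        assert predict_metabolic_rate(winner, 290.0) == \
            predict_metabolic_rate(winner, 290.0, 99.0)

    def test_mass_model_requires_mass(self):
        coef = {"intercept": -4.0, "ln_mass": 0.5, "x": 0.7}
        winner = fit_metabolic_models(make_records(coef))[0]
        with pytest.raises(ValueError):
            predict_metabolic_rate(winner, 290.0)
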