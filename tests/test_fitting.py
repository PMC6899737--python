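import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from thermofr.depletion import FRParams, MortalityParams
from thermofr.fitting import (FRFit, FRModelSpec, ShareStructure, STRUCTURES,
                              enumerate_model_zoo, fit_fr_model, fit_mortality,
                              select_by_bic, trial_neg_log_likelihood)
from thermofr.simulate import (FRDesign, GeneratorTruth, limnophora_design,
                               limnophora_truth, simulate_fr_experiment)
from thermofr.thermal import ArrheniusRate

GEN_SPEC = FRModelSpec("II", ShareStructure("separate", "shared"),
                       ShareStructure("shared", "zero"))


def type1_trials(c, n0, survivors, dataset="a"):
    return pd.DataFrame({
        "dataset_id": [dataset], "predator_present": [True],
        "temperature_C": [10.0], "n0": [n0], "n_survivors": [survivors],
        "duration_days": [1.0]})


class TestTrialLikelihood:
    def test_single_trial_matches_binomial_pmf(self):
        # type I with c = ln 2 gives exactly p_eaten = 1 - e^{-c} = 0.5
        c = float(np.log(2.0))
        trials = type1_trials(c, 10, 5)
        fr = {"a": FRParams("I", ArrheniusRate(c, 0.0))}
        nll = trial_neg_log_likelihood(trials, fr, {"a": MortalityParams()})
        assert nll == pytest.approx(-binom.logpmf(5, 10, 0.5), rel=1e-9)
        assert nll == pytest.approx(1.402, abs=2e-3)

    def test_certain_survival_contributes_nearly_zero(self):
        fr = {"a": FRParams("I", ArrheniusRate(1e-12, 0.0))}
        trials = type1_trials(1e-12, 10, 10)
        nll = trial_neg_log_likelihood(trials, fr, {"a": MortalityParams()})
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_duplicating_the_data_doubles_the_total(self, small_trials, no_mortality):
        fr = {d: FRParams("II", ArrheniusRate(0.5, 0.3), ArrheniusRate(0.1, 0.0))
              for d in ("a", "b")}
        one = trial_neg_log_likelihood(small_trials, fr, no_mortality)
        two = trial_neg_log_likelihood(
            pd.concat([small_trials, small_trials], ignore_index=True),
            fr, no_mortality)
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_invariant_to_row_order_and_relabelling(self, small_trials, no_mortality):
        fr = {"a": FRParams("II", ArrheniusRate(0.5, 0.3), ArrheniusRate(0.1, 0.0)),
              "b": FRParams("II", ArrheniusRate(1.5, 0.0), ArrheniusRate(0.2, 0.0))}
        base = trial_neg_log_likelihood(small_trials, fr, no_mortality)
        shuffled = small_trials.sample(frac=1.0, random_state=1)
        assert trial_neg_log_likelihood(shuffled, fr, no_mortality) == \
            pytest.approx(base, rel=1e-12)
        renamed = small_trials.assign(
            dataset_id=small_trials["dataset_id"].map({"a": "z", "b": "y"}))
        fr2 = {"z": fr["a"], "y": fr["b"]}
        mort2 = {"z": MortalityParams(), "y": MortalityParams()}
        assert trial_neg_log_likelihood(renamed, fr2, mort2) == \
            pytest.approx(base, rel=1e-12)

    def test_invalid_counts_rejected(self, no_mortality):
        bad = type1_trials(1.0, 10, 11)
        fr = {"a": FRParams("I", ArrheniusRate(1.0, 0.0))}
        with pytest.raises(ValueError):
            trial_neg_log_likelihood(bad, fr, no_mortality)


class TestModelZoo:
    @pytest.mark.parametrize("n_datasets", [2, 3])
    def test_cardinality_is_55(self, n_datasets):
        zoo = enumerate_model_zoo(n_datasets)
        assert len(zoo) == 55
        assert len(set(zoo)) == 55

    def test_type_composition(self):
        zoo = enumerate_model_zoo(3)
        by_type = {t: sum(1 for s in zoo if s.fr_type == t) for t in ("I", "II", "III")}
        assert by_type == {"I": 5, "II": 25, "III": 25}

    def test_free_parameter_count_by_construction(self):
        # separate c0 over 3 datasets + shared E_c + shared b0, no E_b -> 5
        assert GEN_SPEC.n_free(3) == 5
        assert GEN_SPEC.n_free(2) == 4
        full = FRModelSpec("III", ShareStructure("separate", "separate"),
                           ShareStructure("separate", "separate"))
        assert full.n_free(3) == 12
        assert FRModelSpec("I", ShareStructure("shared", "zero")).n_free(3) == 1

    def test_separate_energies_require_separate_intercepts(self):
        with pytest.raises(ValueError):
            ShareStructure("shared", "separate")


class TestMortalityFit:
    @staticmethod
    def controls(m0, E_m, n_rep, seed=0):
        design = FRDesign(
            temperatures_C={"d": (4.0, 10.0, 16.0, 18.0)},
            replicates=1, control_replicates=n_rep, dropout_rate=0.0)
        truth = GeneratorTruth(
            fr={"d": FRParams("II", ArrheniusRate(1e-8, 0.0), ArrheniusRate(0.1, 0.0))},
            mort={"d": MortalityParams(m0, E_m)})
        t = simulate_fr_experiment(design, truth, seed=seed)
        return t[~t["predator_present"]]

    def test_zero_deaths_selects_null_model(self):
        ctrl = self.controls(0.0, 0.0, 3)
        fit = fit_mortality(ctrl)
        assert fit.selected["d"].model == "zero"
        assert fit.params_for("d").m0 == 0.0

    def test_constant_rate_recovered_within_ten_percent(self):
        ctrl = self.controls(0.1, 0.0, 60, seed=2)
        fit = fit_mortality(ctrl)
        assert fit.params_for("d").m0 == pytest.approx(0.1, rel=0.10)

    def test_strong_temperature_dependence_wins_bic(self):
        ctrl = self.controls(0.15, 0.6, 80, seed=3)
        fit = fit_mortality(ctrl)
        assert fit.selected["d"].model == "arrhenius"
        assert fit.params_for("d").E_m_eV == pytest.approx(0.6, abs=0.25)


class TestFRModelFit:
    def test_sharing_structures_collapse_with_one_dataset(self):
        design = FRDesign(temperatures_C={"only": (5.0, 10.0, 15.0, 18.0)},
                          replicates=2, dropout_rate=0.0)
        truth = limnophora_truth()
        t = simulate_fr_experiment(
            design, GeneratorTruth(fr={"only": truth.fr["lab2013"]},
                                   mort={"only": MortalityParams()}), seed=4)
        mort = {"only": MortalityParams()}
        shared = FRModelSpec("II", ShareStructure("shared", "shared"),
                             ShareStructure("shared", "zero"))
        separate = FRModelSpec("II", ShareStructure("separate", "shared"),
                               ShareStructure("separate", "zero"))
        f1 = fit_fr_model(shared, t, mort, n_starts=3, seed=0, compute_se=False)
        f2 = fit_fr_model(separate, t, mort, n_starts=3, seed=0, compute_se=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)
        assert f1.params_for("only").attack_coeff.value_at_T0 == \
            pytest.approx(f2.params_for("only").attack_coeff.value_at_T0, rel=1e-3)

    def test_wald_summary_uses_log_scale_for_rates(self):
        design = limnophora_design()
        trials = simulate_fr_experiment(design, limnophora_truth(), seed=5)
        mort = fit_mortality(trials[~trials["predator_present"]])
        fit = fit_fr_model(GEN_SPEC, trials, mort, n_starts=3, seed=0)
        frame = fit.summary_frame()
        assert fit.se is not None
        for _, row in frame.iterrows():
            if row["scale"] == "log":
                assert row["estimate_fitscale"] == \
                    pytest.approx(np.log(row["estimate"]), rel=1e-9)
            assert row["z"] == pytest.approx(row["estimate_fitscale"] / row["se"],
                                             rel=1e-9)
        assert fit.bic == pytest.approx(
            fit.k * np.log(fit.n_obs) - 2.0 * fit.loglik, rel=1e-12)


class TestBICSelection:
    @staticmethod
    def dummy_fit(spec, loglik, k_names, n=100):
        return FRFit(spec=spec, datasets=("a",), param_names=tuple(k_names),
                     param_scales=tuple("log" for _ in k_names),
                     theta=np.zeros(len(k_names)), se=None, loglik=loglik,
                     n_obs=n, bic=len(k_names) * np.log(n) - 2 * loglik,
                     converged=True)

    def test_fewer_parameters_win_at_equal_likelihood(self):
        s1 = FRModelSpec("I", STRUCTURES[0])
        s2 = FRModelSpec("I", STRUCTURES[2])
        f3 = self.dummy_fit(s1, -50.0, ["a", "b", "c"])
        f5 = self.dummy_fit(s2, -50.0, ["a", "b", "c", "d", "e"])
        sel = select_by_bic([f5, f3])
        assert sel.winner is f3
        assert f5.bic - f3.bic == pytest.approx(2 * np.log(100), rel=1e-12)

    def test_single_fit_is_returned_as_winner(self):
        f = self.dummy_fit(FRModelSpec("I", STRUCTURES[0]), -10.0, ["a"])
        assert select_by_bic([f]).winner is f

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_by_bic([])

    def test_failed_fits_are_excluded(self):
        good = self.dummy_fit(FRModelSpec("I", STRUCTURES[0]), -10.0, ["a"])
        bad = FRFit(spec=FRModelSpec("I", STRUCTURES[1]), datasets=("a",),
                    param_names=("a",), param_scales=("log",),
                    theta=np.array([np.nan]), se=None, loglik=-np.inf,
                    n_obs=100, bic=np.inf, converged=False)
        assert select_by_bic([bad, good]).winner is good
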