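"""Scaling fits: exact recovery, reparameterization, BIC selection,
effect tests and mass-normalization."""

import numpy as np
import pandas as pd
import pytest

from allometherm import (DataError, DomainError, GeneratorConfig,
                         InsufficientDataError, compare_models_bic,
                         fit_scaling_mixed, fit_scaling_simple,
                         generate_cohort, mass_normalize,
                         simulate_scaling_observations, simulate_ventricles)
from allometherm import test_effects as effects_table

MMR_SLOPE = 0.810
MMR_INTERCEPTS = {12.0: 1.011, 16.0: 1.235, 20.0: 1.436, 22.0: 1.497}


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(seed=1))


def observations(cohort, *, slope=MMR_SLOPE, intercepts=MMR_INTERCEPTS,
                 ind_sd=0.10, res_sd=0.10, seed=5, n_obs=None):
    rng = np.random.default_rng(seed)
    df, _ = simulate_scaling_observations(cohort, slope, intercepts,
                                          ind_sd, res_sd, rng, n_obs=n_obs)
    return df


class TestMixedFit:
    def test_noiseless_recovery_of_slope_and_intercepts(self, cohort):
        df = observations(cohort, ind_sd=0.0, res_sd=0.0)
        fit = fit_scaling_mixed(df, "mmr")
        assert fit.slope == pytest.approx(MMR_SLOPE, abs=1e-9)
        for t, a in MMR_INTERCEPTS.items():
            assert fit.intercepts[t] == pytest.approx(a, abs=1e-9)
        assert "zero_residual_degenerate" in fit.warnings

    def test_mass_unit_change_shifts_only_intercepts(self, cohort):
        df = observations(cohort)
        fit_kg = fit_scaling_mixed(df, "mmr")
        df_g = df.copy()
        df_g["ln_mass"] = df_g["ln_mass"] + np.log(1000.0)  # grams
        fit_g = fit_scaling_mixed(df_g, "mmr")
        assert fit_g.slope == pytest.approx(fit_kg.slope, abs=1e-6)
        for t in MMR_INTERCEPTS:
            shift = fit_kg.intercepts[t] - fit_g.intercepts[t]
            assert shift == pytest.approx(fit_kg.slope * np.log(1000.0),
                                          abs=1e-5)

    def test_single_temperature_matches_ols(self, cohort):
        df = observations(cohort, intercepts={16.0: 1.235}, ind_sd=0.0)
        fit = fit_scaling_mixed(df, "mmr")
        ols = fit_scaling_simple(df.rename(columns={})[
            ["ln_mass", "ln_response"]], "mmr")
        assert fit.slope == pytest.approx(ols.slope, abs=1e-5)
        assert len(fit.intercepts) == 1

    def test_nonfinite_response_rejected(self, cohort):
        df = observations(cohort)
        df.loc[0, "ln_response"] = np.inf
        with pytest.raises(DataError):
            fit_scaling_mixed(df, "mmr")

    def test_recovery_with_noise_at_study_size(self, cohort):
        df = observations(cohort, n_obs=238, seed=17)
        fit = fit_scaling_mixed(df, "mmr")
        assert fit.slope == pytest.approx(MMR_SLOPE, abs=3 * fit.slope_se)
        assert fit.n_observations == 238
        assert fit.n_individuals <= 83


class TestSimpleFit:
    def test_exact_line_recovered(self):
        x = np.linspace(-5.0, -1.0, 10)
        df = pd.DataFrame({"ln_mass": x, "ln_response": 3.359 + 0.030 * x})
        fit = fit_scaling_simple(df, "t_arr")
        assert fit.slope == pytest.approx(0.030, abs=1e-12)
        assert fit.intercept == pytest.approx(3.359, abs=1e-12)

    def test_midpoint_interpolation(self):
        x = np.array([-4.0, -2.0, -3.0])
        df = pd.DataFrame({"ln_mass": x, "ln_response": 1.0 + 0.5 * x})
        fit = fit_scaling_simple(df)
        assert fit.slope == pytest.approx(0.5)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_ventricle_recovery_within_two_se(self):
        cfg = GeneratorConfig(n_fish=30, seed=23)
        cohort = generate_cohort(cfg)
        vm = simulate_ventricles(cohort, cfg)
        df = pd.DataFrame({
            "ln_mass": np.log([f.body_mass for f in cohort]),
            "ln_response": np.log(vm["ventricle_mass_kg"]),
        })
        fit = fit_scaling_simple(df, "vm")
        assert abs(fit.slope - cfg.vm_slope) <= 2 * fit.slope_se

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"ln_mass": [1.0, 1.0, 1.0],
                           "ln_response": [0.1, 0.2, 0.3]})
        with pytest.raises(DataError):
            fit_scaling_simple(df)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"ln_mass": [1.0, 2.0], "ln_response": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            fit_scaling_simple(df)


class TestModelComparison:
    CANDIDATES = [dict(name="additive"),
                  dict(name="interaction", interaction=True)]

    def test_additive_truth_selects_additive_model(self, cohort):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = observations(cohort, seed=100 + seed, n_obs=238)
            mc = compare_models_bic(df, self.CANDIDATES, "mmr")
            wins += mc.selected == "additive"
        assert wins >= 0.9 * n_seeds

    def test_strong_interaction_selects_interaction_model(self, cohort):
        rng = np.random.default_rng(3)
        slopes = {12.0: 0.70, 16.0: 0.81, 20.0: 0.92, 22.0: 1.02}
        rows = []
        for f in cohort:
            u = 0.10 * rng.standard_normal()
            for t, a in MMR_INTERCEPTS.items():
                ln_y = (a + slopes[t] * np.log(f.body_mass) + u
                        + 0.10 * rng.standard_normal())
                rows.append((f.fish_id, np.log(f.body_mass), t, ln_y))
        df = pd.DataFrame(rows, columns=["fish_id", "ln_mass",
                                         "temperature", "ln_response"])
        mc = compare_models_bic(df, self.CANDIDATES, "mmr")
        assert mc.selected == "interaction"

    def test_tied_candidates_resolved_by_order(self, cohort):
        df = observations(cohort, seed=7)
        mc = compare_models_bic(df, [dict(name="first"), dict(name="second")])
        bics = mc.table.set_index("model")["bic"]
        assert bics["first"] == pytest.approx(bics["second"])
        assert mc.selected == "first"
        assert (mc.table["delta_bic"].dropna() >= 0).all()


class TestEffectTests:
    def test_equal_intercepts_noiseless_gives_null_result(self, cohort):
        flat = {t: 1.0 for t in MMR_INTERCEPTS}
        df = observations(cohort, intercepts=flat, ind_sd=0.10, res_sd=0.10,
                          seed=19)
        # force exactly equal level means by removing the temperature signal
        fit = fit_scaling_mixed(df, "mmr")
        eff = effects_table(fit)
        p_temp = eff.terms.set_index("term").loc["temperature", "p"]
        assert p_temp > 0.05
        assert (eff.contrasts["p_adj"] > 0.05).all()

    def test_temperature_spread_strongly_significant(self, cohort):
        df = observations(cohort, seed=29, n_obs=238)
        eff = effects_table(fit_scaling_mixed(df, "mmr"))
        terms = eff.terms.set_index("term")
        assert terms.loc["temperature", "p"] < 1e-3
        assert terms.loc["ln_mass", "p"] < 1e-3
        assert len(eff.contrasts) == 6   # all temperature pairs

    def test_absent_term_not_reported(self):
        x = np.linspace(-5.0, -1.0, 10)
        df = pd.DataFrame({"ln_mass": x, "ln_response": 3.0 + 0.1 * x})
        eff = effects_table(fit_scaling_simple(df, "t_ab"))
        assert set(eff.terms["term"]) == {"ln_mass"}
        assert eff.contrasts.empty


class TestMassNormalize:
    def test_identity_at_reference_mass(self):
        assert mass_normalize(0.3, 0.065, 0.81) == pytest.approx(0.3 / 0.065)

    def test_printed_group_mean_reproduced(self):
        whole = np.exp(1.011 + 0.810 * np.log(0.065))
        assert mass_normalize(whole, 0.065, 0.810) == pytest.approx(4.62,
                                                                    abs=0.01)

    def test_exponent_zero_removes_mass_dependence(self):
        a = mass_normalize(2.0, 0.010, 0.0)
        b = mass_normalize(2.0, 0.500, 0.0)
        assert a == b == pytest.approx(2.0 / 0.065)

    def test_normalize_then_refit_gives_zero_slope(self, cohort):
        df = observations(cohort, ind_sd=0.0, res_sd=0.0,
                          intercepts={16.0: 1.235})
        fit = fit_scaling_mixed(df, "mmr")
        norm = [mass_normalize(np.exp(y), np.exp(m), fit.slope)
                for y, m in zip(df["ln_response"], df["ln_mass"])]
        refit = fit_scaling_simple(pd.DataFrame({
            "ln_mass": df["ln_mass"], "ln_response": np.log(norm)}))
        assert abs(refit.slope) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            mass_normalize(-1.0, 0.1, 0.8)
        with pytest.raises(DomainError):
            mass_normalize(1.0, 0.0, 0.8)
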