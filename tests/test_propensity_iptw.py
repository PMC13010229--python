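"""Propensity fitting, combined weights, the IPTW estimator and balance."""

import numpy as np
import pandas as pd
import pytest

import svypate as sp
from svypate.propensity_iptw import (
    PositivityWarning,
    balance_smd,
    compute_iptw_weights,
    estimate_iptw_pate,
    fit_propensity,
)
from svypate.survey_design import SeparationError, SurveyDataset

from conftest import standardization_oracle


def _confounded_frame(n=4000, seed=2):
    rng = np.random.default_rng(seed)
    L = rng.binomial(1, 0.4, n)
    pi = np.where(L == 1, 0.6, 0.2)
    A = rng.binomial(1, pi)
    Y = 50 + 3 * L + 2 * A + rng.normal(0, 1, n)
    return pd.DataFrame({"Y": Y, "A": A, "L": L, "weight": 1.0})


class TestFitPropensity:
    def test_intercept_only_recovers_prevalence(self):
        df = _confounded_frame(n=5000)
        data = SurveyDataset(data=df)
        prop = fit_propensity(data, "1")
        np.testing.assert_allclose(prop.pi, df["A"].mean(), rtol=1e-8)

    def test_saturated_model_reproduces_cell_rates(self):
        df = _confounded_frame(n=5000)
        data = SurveyDataset(data=df)
        prop = fit_propensity(data, "C(L)")
        for lvl in (0, 1):
            mask = df["L"] == lvl
            np.testing.assert_allclose(
                prop.pi[mask], df.loc[mask, "A"].mean(), rtol=1e-7
            )

    def test_all_exposed_raises_separation_error(self):
        df = _confounded_frame(n=100).assign(A=1)
        with pytest.raises(SeparationError):
            fit_propensity(SurveyDataset(data=df), "L")

    def test_outcome_in_formula_rejected(self):
        data = SurveyDataset(data=_confounded_frame(n=100))
        with pytest.raises(ValueError, match="outcome"):
            fit_propensity(data, "L + Y")

    def test_extreme_scores_emit_positivity_warning(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.normal(0, 2, n)
        a = rng.binomial(1, 1 / (1 + np.exp(-2.0 * x)))
        df = pd.DataFrame({"Y": rng.normal(size=n), "A": a, "x": x, "weight": 1.0})
        with pytest.warns(PositivityWarning):
            fit_propensity(SurveyDataset(data=df), "x")


class TestCombinedWeights:
    def test_treatment_weight_formula(self):
        df = pd.DataFrame(
            {"Y": [1.0, 2.0], "A": [1, 0], "weight": [1.0, 1.0]}
        )
        data = SurveyDataset(data=df)
        prop = sp.fit_propensity(data, "1")
        cw = compute_iptw_weights(prop, data)
        # pi = 0.5 for both: exposed t = 1/0.5 = 2, unexposed t = 1/0.5 = 2
        np.testing.assert_allclose(cw.treatment, [2.0, 2.0])
        np.testing.assert_allclose(cw.analysis, cw.treatment)

    def test_analysis_weight_is_product_of_treatment_and_survey_weight(self):
        # exposed with pi = 0.25 and omega = 3 -> w = 4 * 3 = 12
        from svypate.propensity_iptw import PropensityResult
        from svypate.survey_design import fit_weighted_glm

        df = pd.DataFrame(
            {"Y": [0.0] * 4, "A": [1, 1, 0, 0], "weight": [3.0, 3.0, 1.0, 1.0]}
        )
        data = SurveyDataset(data=df)
        fit = fit_weighted_glm(data, "A ~ 1", family="logistic", weights_mode="none")
        prop = PropensityResult(
            pi=np.array([0.25, 0.25, 0.25, 0.25]), fit=fit, survey_weighted=False
        )
        cw = compute_iptw_weights(prop, data)
        np.testing.assert_allclose(cw.analysis[:2], 12.0)
        np.testing.assert_allclose(cw.analysis[2:], 1 / 0.75)

    def test_truncation_counts_capped_values(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        a = rng.binomial(1, 1 / (1 + np.exp(-x)))
        df = pd.DataFrame({"Y": rng.normal(size=n), "A": a, "x": x, "weight": 1.0})
        data = SurveyDataset(data=df)
        prop = fit_propensity(data, "x")
        cw_off = compute_iptw_weights(prop, data)
        assert cw_off.n_capped == 0
        cw_on = compute_iptw_weights(prop, data, truncation_quantile=0.1)
        assert cw_on.n_capped > 0
        assert cw_on.treatment.max() <= cw_off.treatment.max()

    def test_pseudo_population_size_identity(self):
        """sum over exposed of 1/pi estimates n (E[A/pi] = 1)."""
        df = _confounded_frame(n=8000, seed=9)
        data = SurveyDataset(data=df)
        prop = fit_propensity(data, "C(L)")
        cw = compute_iptw_weights(prop, data)
        total = cw.treatment[df["A"] == 1].sum()
        assert total == pytest.approx(len(df), rel=0.02)


class TestEstimateIPTW:
    def test_randomized_exposure_reduces_to_difference_in_means(self):
        rng = np.random.default_rng(3)
        n = 2000
        df = pd.DataFrame(
            {
                "A": rng.binomial(1, 0.5, n),
                "x": rng.normal(size=n),
                "weight": 1.0,
            }
        )
        df["Y"] = 1.5 * df["A"] + rng.normal(size=n)
        data = SurveyDataset(data=df)
        res = estimate_iptw_pate(data, "1", use_survey_weights=False)
        diff = df.loc[df.A == 1, "Y"].mean() - df.loc[df.A == 0, "Y"].mean()
        assert res.estimate == pytest.approx(diff, rel=1e-9)

    def test_matches_standardization_oracle_on_discrete_data(self, discrete_data):
        res = estimate_iptw_pate(discrete_data, "C(L)", use_survey_weights=False)
        assert res.estimate == pytest.approx(
            standardization_oracle(discrete_data), rel=1e-10
        )

    def test_matches_weighted_standardization_oracle(self, discrete_data_weighted):
        """With survey weights, saturated IPTW equals standardization over
        the omega-weighted confounder distribution (propensity fitted with
        omega so the cell scores are the weighted exposure rates)."""
        res = estimate_iptw_pate(
            discrete_data_weighted, "C(L)",
            use_survey_weights=True, propensity_survey_weighted=True,
        )
        assert res.estimate == pytest.approx(
            standardization_oracle(discrete_data_weighted), rel=1e-10
        )

    def test_metadata_records_weighting_choices(self, discrete_data):
        res = estimate_iptw_pate(discrete_data, "C(L)", truncation_quantile=0.05)
        assert res.method == "IPTW"
        assert res.estimand == "marginal"
        assert res.metadata["truncation_quantile"] == 0.05
        assert res.ci_lower <= res.estimate <= res.ci_upper


class TestBalance:
    def test_identical_distributions_give_zero_smd(self):
        df = pd.DataFrame(
            {
                "Y": np.zeros(8),
                "A": [0, 0, 0, 0, 1, 1, 1, 1],
                "x": [1.0, 2.0, 3.0, 4.0] * 2,
                "weight": 1.0,
            }
        )
        tab = balance_smd(SurveyDataset(data=df), ["x"])
        assert tab.loc[0, "smd_unweighted"] == pytest.approx(0.0, abs=1e-12)

    def test_smd_formula_mean_difference_over_pooled_sd(self):
        # arm means 1 vs 2; both arms have SD 2 -> pooled SD 2 -> SMD 0.5
        arm0 = np.array([-1.0, 3.0, -1.0, 3.0]) - 0.0  # mean 1... adjust below
        arm0 = np.array([-1.0, 3.0, 1.0, 1.0])  # mean 1, var 8/3
        # construct exactly: use values with known mean/sd
        a0 = np.array([1 - 2.0, 1 + 2.0, 1 - 2.0, 1 + 2.0])  # mean 1, sd 2.3094
        a1 = a0 + 1.0  # mean 2, same spread
        df = pd.DataFrame(
            {
                "Y": np.zeros(8),
                "A": [0] * 4 + [1] * 4,
                "x": np.concatenate([a0, a1]),
                "weight": 1.0,
            }
        )
        tab = balance_smd(SurveyDataset(data=df), ["x"])
        pooled = np.sqrt((a0.var(ddof=1) + a1.var(ddof=1)) / 2)
        assert tab.loc[0, "smd_unweighted"] == pytest.approx(1.0 / pooled)

    def test_zero_variance_covariate_reported_as_nan(self):
        df = pd.DataFrame(
            {"Y": np.zeros(6), "A": [0, 0, 0, 1, 1, 1], "x": 1.0, "weight": 1.0}
        )
        tab = balance_smd(SurveyDataset(data=df), ["x"])
        assert np.isnan(tab.loc[0, "smd_unweighted"])

    def test_iptw_weighting_balances_confounders(self, default_sample):
        """After weighting by t (well-specified propensity), max |SMD| < 0.1."""
        prop = fit_propensity(default_sample, "age + income + sex + C(eth)")
        cw = compute_iptw_weights(prop, default_sample)
        tab = balance_smd(
            default_sample, ["age", "income", "sex", "eth"], weights=cw.treatment
        )
        before = tab["smd_unweighted"].abs().max()
        after = tab["smd_weighted"].abs().max()
        assert after < 0.1
        assert after < before
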