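"""Prediction tests: linear predictor arithmetic, marginal probabilities,
conditional prediction against the Gaussian-conditioning oracle, scenarios
and expected richness."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from jstdm.prediction import (
    Scenario,
    expected_richness,
    linear_predictor,
    predict_conditional,
    predict_marginal,
    scenario_predict,
)
from jstdm.sampler import PosteriorSampleSet

from conftest import lognormal_design


def _const_samples(beta, Lambda, sigma2, n_draws=1):
    """A sample set whose draws all equal the given parameter values."""
    beta = np.asarray(beta, float)
    Lambda = np.asarray(Lambda, float)
    sigma2 = np.asarray(sigma2, float)
    nc, p = beta.shape
    return PosteriorSampleSet(
        beta=np.tile(beta, (1, n_draws, 1, 1)),
        gamma=np.zeros((1, n_draws, nc, 1)),
        V=np.tile(np.eye(nc), (1, n_draws, 1, 1)),
        Lambda=np.tile(Lambda, (1, n_draws, 1, 1)),
        sigma2=np.tile(sigma2, (1, n_draws, 1)),
        H=None,
    )


class TestLinearPredictor:
    def test_zero_factor_scores_reduce_to_xbeta(self):
        rng = np.random.default_rng(0)
        X, B = rng.standard_normal((5, 3)), rng.standard_normal((3, 4))
        L = linear_predictor(B, rng.standard_normal((2, 4)), X, np.zeros((5, 2)))
        np.testing.assert_allclose(L, X @ B)

    def test_intercept_only_rows_identical(self):
        B = np.array([[1.0, -2.0]])
        L = linear_predictor(B, np.zeros((0, 2)), np.ones((4, 1)), np.zeros((4, 0)))
        assert np.all(L == L[0])

    def test_matches_elementwise_double_sum(self):
        rng = np.random.default_rng(1)
        X, B = rng.standard_normal((3, 2)), rng.standard_normal((2, 5))
        H, Lam = rng.standard_normal((3, 2)), rng.standard_normal((2, 5))
        L = linear_predictor(B, Lam, X, H)
        for i in range(3):
            for c in range(5):
                expect = sum(X[i, k] * B[k, c] for k in range(2)) + sum(
                    H[i, f] * Lam[f, c] for f in range(2)
                )
                assert np.isclose(L[i, c], expect)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            linear_predictor(np.zeros((2, 3)), np.zeros((1, 3)), np.ones((4, 3)), np.zeros((4, 1)))


class TestMarginal:
    def _pa_design(self):
        from jstdm.design import (
            EnvironmentalDesign, ModelDesign, MultiResponseMatrix,
            SpeciesTraitMatrix, expand_trait_design,
        )
        from jstdm.responses import ResponseType

        rt = [ResponseType("PA", "bernoulli_probit", "identity", "occurrence")]
        Y = MultiResponseMatrix(
            np.ones((3, 1)), np.ones((3, 1), bool), [0, 1, 2], ["s"], rt,
            np.zeros(1), np.ones(1),
        )
        env = EnvironmentalDesign.intercept_only(Y.site_ids)
        T = SpeciesTraitMatrix.intercept_only(["s"])
        return ModelDesign(Y, env, T, expand_trait_design(T, rt))

    def test_zero_parameters_give_probability_half(self):
        design = self._pa_design()
        s = _const_samples(np.zeros((1, 1)), np.zeros((1, 1)), np.ones(1), n_draws=50)
        p = predict_marginal(s, design, seed=0)
        np.testing.assert_allclose(p.mean_response, 0.5)

    def test_probit_intercept_maps_through_normal_cdf(self):
        design = self._pa_design()
        s = _const_samples(np.array([[1.6449]]), np.zeros((0, 1)), np.ones(1))
        p = predict_marginal(s, design, seed=0)
        np.testing.assert_allclose(p.mean_response, 0.95, atol=1e-4)

    def test_median_backtransform_is_exp_of_linear(self):
        design = lognormal_design(4, 1, seed=2)
        s = _const_samples(np.array([[0.7]]), np.zeros((0, 1)), np.array([0.4]))
        p = predict_marginal(s, design, seed=0, backtransform="median")
        np.testing.assert_allclose(p.mean_response, np.exp(0.7))
        pm = predict_marginal(s, design, seed=0, backtransform="mean")
        np.testing.assert_allclose(pm.mean_response, np.exp(0.7 + 0.2))


class TestConditional:
    def test_zero_loadings_conditional_equals_marginal_in_distribution(self):
        """With no shared loadings no information can flow from the
        conditioned column: predictive draws must match marginal ones."""
        design = lognormal_design(1, 2, seed=3)
        beta = np.array([[0.5, -0.2]])
        s = _const_samples(beta, np.zeros((1, 2)), np.array([0.3, 0.3]), n_draws=2000)
        cond = {("s1", "T1"): 2.0}
        pc = predict_conditional(s, design, np.ones((1, 1)), cond, seed=4,
                                 n_inner=5, n_discard=2)
        pm = predict_marginal(s, design, np.ones((1, 1)), seed=5)
        ks = stats.ks_2samp(pc.linear[:, 0, 1], pm.linear[:, 0, 1])
        assert ks.pvalue > 0.01
        np.testing.assert_allclose(pc.linear[:, 0, 1], beta[0, 1])

    def test_matches_bivariate_normal_conditioning(self):
        """2 log-normal columns sharing 1 factor: the conditional predictive
        mean must equal the closed-form Gaussian conditional mean."""
        design = lognormal_design(3, 2, seed=6)
        lam = np.array([[0.9, 0.7]])
        sig2 = np.array([0.25, 0.36])
        beta = np.array([[0.5, -0.2]])
        s = _const_samples(beta, lam, sig2, n_draws=400)
        v1 = 1.8
        pc = predict_conditional(s, design, np.ones((3, 1)), {("s1", "T1"): v1},
                                 seed=7, n_inner=50, n_discard=20)
        y1 = np.log(v1)
        slope = lam[0, 0] * lam[0, 1] / (lam[0, 0] ** 2 + sig2[0])
        oracle = beta[0, 1] + slope * (y1 - beta[0, 0])
        est = pc.linear[:, :, 1]
        se = est.std() / np.sqrt(est.shape[0])
        assert abs(est.mean() - oracle) < 3 * se

        var_oracle = lam[0, 1] ** 2 * (1 - lam[0, 0] ** 2 / (lam[0, 0] ** 2 + sig2[0]))
        assert np.isclose(est.var(), var_oracle, rtol=0.25)

    def test_conditioning_on_high_abundance_raises_linked_trait(self):
        """Positive shared loading: a high conditioned value must pull the
        predicted linked column up relative to a low conditioned value."""
        design = lognormal_design(2, 2, seed=8)
        s = _const_samples(np.zeros((1, 2)), np.array([[0.9, 0.8]]),
                           np.array([0.2, 0.2]), n_draws=300)
        hi = predict_conditional(s, design, np.ones((2, 1)), {("s1", "T1"): 8.0}, seed=9)
        lo = predict_conditional(s, design, np.ones((2, 1)), {("s1", "T1"): 0.2}, seed=9)
        assert hi.mean_linear[0, 1] > lo.mean_linear[0, 1] + 0.5

    def test_conditioning_everything_or_nothing_errors(self):
        design = lognormal_design(2, 2, seed=10)
        s = _const_samples(np.zeros((1, 2)), np.zeros((1, 2)), np.ones(2))
        with pytest.raises(ValueError, match="nonempty"):
            predict_conditional(s, design, np.ones((1, 1)), {})
        with pytest.raises(ValueError, match="every column"):
            predict_conditional(s, design, np.ones((1, 1)),
                                {("s1", "T1"): 1.0, ("s1", "T2"): 1.0})


class TestRichness:
    def test_half_probabilities_sum_to_one(self):
        out = expected_richness(np.full((10, 2), 0.5))
        np.testing.assert_allclose(out["per_draw"], 1.0)

    def test_certain_occurrences_give_species_count(self):
        out = expected_richness(np.ones((5, 7)))
        np.testing.assert_allclose(out["mean"], 7.0)

    def test_mean_commutes_with_summation(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=(40, 6))
        out = expected_richness(p)
        assert np.isclose(out["mean"], p.sum(axis=1).mean())

    def test_bounded_by_species_count_and_order_invariant(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=(30, 4, 9))
        out = expected_richness(p)
        assert np.all(out["per_draw"] <= 9.0 + 1e-12)
        perm = rng.permutation(9)
        out2 = expected_richness(p[:, :, perm])
        np.testing.assert_allclose(out["per_draw"], out2["per_draw"])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            expected_richness(np.array([[1.2, 0.5]]))


class TestScenario:
    def test_empty_scenario_is_marginal_prediction(self, small_fit, small_design):
        res = scenario_predict(small_fit, small_design, Scenario(), seed=3, n_draws=40)
        pm = predict_marginal(small_fit, small_design, seed=3, n_draws=40)
        blk = small_design.Y.block_slice("PA")
        np.testing.assert_allclose(
            res.occurrence.to_numpy(), pm.response[:, :, blk].mean(axis=0)
        )

    def test_focal_species_excluded_from_summary(self, small_fit, small_design):
        focal = small_design.Y.species[0]
        scen = Scenario(condition={(focal, "PA"): 1.0}, focal_species=focal)
        res = scenario_predict(small_fit, small_design, scen, seed=4, n_draws=30)
        assert focal not in res.occurrence.columns
        assert res.occurrence.shape[1] == small_design.Y.n_species - 1

    def test_covariate_override_uses_quantiles(self, small_fit, small_design):
        name = small_design.env.covariate_names[0]
        scen = Scenario(covariates={name: "high"})
        res = scenario_predict(small_fit, small_design, scen, seed=5, n_draws=30)
        ref = pd.DataFrame(
            small_design.env.original_scale(),
            index=small_design.env.site_ids,
            columns=small_design.env.covariate_names,
        )
        ref[name] = ref[name].quantile(0.9)
        pm = predict_marginal(small_fit, small_design, ref, seed=5, n_draws=30)
        blk = small_design.Y.block_slice("PA")
        np.testing.assert_allclose(
            res.occurrence.to_numpy(), pm.response[:, :, blk].mean(axis=0)
        )

    def test_negative_association_lowers_richness_when_focal_present(self):
        """Constructed loadings: the focal ABUC column loads +, every other
        occurrence column loads -, so conditioning the focal presence and
        high abundance must depress expected richness."""
        from jstdm.design import (
            EnvironmentalDesign, ModelDesign, MultiResponseMatrix,
            SpeciesTraitMatrix, expand_trait_design,
        )
        from jstdm.responses import case_study_rtypes

        rt = case_study_rtypes(())  # PA + ABUC
        species = ["focal", "n1", "n2"]
        n_cols = 6
        Y = MultiResponseMatrix(
            np.tile([1, 1, 1, 0.0, 0.0, 0.0], (4, 1)), np.ones((4, n_cols), bool),
            [0, 1, 2, 3], species, rt, np.zeros(n_cols), np.ones(n_cols),
        )
        env = EnvironmentalDesign.intercept_only(Y.site_ids)
        T = SpeciesTraitMatrix.intercept_only(species)
        design = ModelDesign(Y, env, T, expand_trait_design(T, rt))
        Lam = np.zeros((1, n_cols))
        Lam[0, Y.col_index("focal", "ABUC")] = 1.0
        Lam[0, Y.col_index("focal", "PA")] = 1.0
        Lam[0, Y.col_index("n1", "PA")] = -0.9
        Lam[0, Y.col_index("n2", "PA")] = -0.9
        s = _const_samples(np.zeros((1, n_cols)), Lam, np.where(design.Y.is_probit, 1.0, 0.2),
                           n_draws=300)
        present = Scenario(condition={("focal", "PA"): 1.0, ("focal", "ABUC"): 20.0},
                           focal_species="focal")
        absent = Scenario(condition={("focal", "PA"): 0.0}, focal_species="focal")
        r1 = scenario_predict(s, design, present, seed=6)
        r0 = scenario_predict(s, design, absent, seed=6)
        assert r1.richness_mean < r0.richness_mean - 0.2

    def test_unknown_names_rejected(self, small_fit, small_design):
        with pytest.raises(ValueError, match="covariate"):
            scenario_predict(small_fit, small_design, Scenario(covariates={"bogus": 1.0}), seed=0)
        with pytest.raises(ValueError, match="unknown"):
            scenario_predict(
                small_fit, small_design,
                Scenario(condition={("nosuch", "PA"): 1.0}), seed=0,
            )
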