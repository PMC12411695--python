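"""Sampler tests: conjugate full conditionals against closed forms,
augmentation truncation, shrinkage structure, chain bookkeeping and
missing-data exactness."""

import numpy as np
import pytest

from jstdm.design import (
    EnvironmentalDesign,
    ModelDesign,
    MultiResponseMatrix,
    SpeciesTraitMatrix,
    expand_trait_design,
)
from jstdm.priors import PriorConfig
from jstdm.responses import ResponseType, case_study_rtypes
from jstdm.sampler import (
    SamplerWorkspace,
    _inv_wishart,
    _trunc_normal,
    beta_conditional_moments,
    convergence_diagnostics,
    init_state,
    run_mcmc,
    update_beta_gamma,
    update_factors,
    update_sigma,
)
from jstdm.synthetic import generate_community, generate_parameters

from conftest import lognormal_design


class TestInit:
    def test_deterministic_under_seed(self, small_design):
        a = init_state(small_design, PriorConfig(n_factors=2), 7)
        b = init_state(small_design, PriorConfig(n_factors=2), 7)
        for f in ("beta", "H", "Lambda", "sigma2", "z"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_intercept_only_initial_beta_is_column_mean(self):
        design = lognormal_design(50, 1, seed=4)
        y = np.random.default_rng(0).normal(2.0, 0.5, size=50)
        design.Y.values[:, 0] = y
        st = init_state(design, PriorConfig(n_factors=0), 0)
        assert np.isclose(st.beta[0, 0], y.mean(), atol=1e-3)

    def test_probit_latents_sign_consistent(self, small_design):
        st = init_state(small_design, PriorConfig(n_factors=2), 0)
        pa = small_design.Y.block_slice("PA")
        y = small_design.Y.values[:, pa]
        z = st.z[:, pa]
        assert np.all(z[y == 1] > 0)
        assert np.all(z[y == 0] <= 0)


class TestTruncatedNormal:
    def test_mean_at_zero_location(self):
        rng = np.random.default_rng(0)
        w = _trunc_normal(np.zeros(200_000), np.ones(200_000, bool), rng)
        assert np.all(w > 0)
        assert np.isclose(w.mean(), np.sqrt(2 / np.pi), atol=0.01)

    def test_negative_branch_never_positive(self):
        rng = np.random.default_rng(1)
        loc = rng.normal(size=10_000)
        w = _trunc_normal(loc, np.zeros(10_000, bool), rng)
        assert np.all(w <= 0)

    def test_far_positive_location_returns_location(self):
        rng = np.random.default_rng(2)
        w = _trunc_normal(np.full(20_000, 30.0), np.ones(20_000, bool), rng)
        assert np.isclose(w.mean(), 30.0, atol=0.05)


class TestConjugateOracles:
    def test_beta_full_conditional_matches_bayesian_regression(self):
        """Factors disabled, V = I, sigma2 = 1: the full conditional must be
        the textbook normal-prior Bayesian regression posterior."""
        rng = np.random.default_rng(5)
        n, nc = 40, 3
        design = lognormal_design(n, 1, seed=5)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, nc - 1))])
        design.env.X = X
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.standard_normal(n)
        design.Y.values[:, 0] = y
        st = init_state(design, PriorConfig(n_factors=0), 0)
        st.V = np.eye(nc)
        st.sigma2 = np.ones(1)
        st.gamma = np.zeros_like(st.gamma)
        mean, cov = beta_conditional_moments(st, design)
        prec = np.eye(nc) + X.T @ X
        np.testing.assert_allclose(mean[:, 0], np.linalg.solve(prec, X.T @ y), atol=1e-10)
        np.testing.assert_allclose(cov[0], np.linalg.inv(prec), atol=1e-10)

    def test_no_data_column_draws_beta_from_prior_conditional(self):
        design = lognormal_design(30, 2, seed=6)
        design.Y.observed[:, 1] = False          # second column fully missing
        design.Y.values[~design.Y.observed] = np.nan
        st = init_state(design, PriorConfig(n_factors=0), 0)
        st.V = 0.5 * np.eye(1)
        st.gamma = np.array([[1.5, -2.0]])
        mean, cov = beta_conditional_moments(st, design)
        # missing cells contribute nothing: conditional = prior N(mu, V)
        assert np.isclose(mean[0, 1], -2.0)
        assert np.isclose(cov[1][0, 0], 0.5)

    def test_gamma_reduces_to_grand_mean_with_intercept_trait_design(self):
        """T intercept-only and V fixed: the trait-effect posterior mean is a
        shrunk grand mean of the environmental responses across columns."""
        design = lognormal_design(20, 3, species=("a", "b"), seed=7)
        ws = SamplerWorkspace.from_design(design)
        st = init_state(ws, PriorConfig(n_factors=0), 0)
        st.beta = np.array([[1.0, 3.0, -2.0, 4.0, 0.5, 2.5]])
        means = []
        rng_draws = np.random.default_rng(8)
        priors = PriorConfig(n_factors=0, gamma_scale=100.0, v_df=50, v_scale=50.0)
        for _ in range(3000):
            s = st.copy()
            update_beta_gamma(s, ws, priors, rng_draws)
            means.append(s.gamma.copy())
        got = np.mean(means, axis=0)
        # with a flat gamma prior the conditional mean given beta is the
        # per-type mean of beta over that type's columns
        expect = st.beta.reshape(1, 3, 2).mean(axis=2)
        np.testing.assert_allclose(got, expect, atol=0.1)

    def test_sigma_posterior_moment_matches_inverse_gamma(self):
        design = lognormal_design(25, 1, seed=9)
        ws = SamplerWorkspace.from_design(design)
        st = init_state(ws, PriorConfig(n_factors=0), 0)
        st.beta = np.zeros_like(st.beta)
        resid = design.Y.values[:, 0]
        shape = 1.0 + 25 / 2
        rate = 0.1 + 0.5 * np.sum(resid**2)
        rng = np.random.default_rng(10)
        pr = PriorConfig(n_factors=0)
        draws = []
        for _ in range(10_000):
            s = st.copy()
            update_sigma(s, ws, pr, rng)
            draws.append(s.sigma2[0])
        analytic = rate / (shape - 1)
        assert np.isclose(np.mean(draws), analytic, rtol=0.05)

    def test_inverse_wishart_sampler_mean(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        df = 10.0
        rng = np.random.default_rng(11)
        draws = np.mean([_inv_wishart(df, S, rng) for _ in range(20_000)], axis=0)
        np.testing.assert_allclose(draws, S / (df - 2 - 1), rtol=0.05)


class TestFactors:
    def test_zero_loadings_give_prior_factor_scores(self):
        design = lognormal_design(400, 1, seed=12)
        ws = SamplerWorkspace.from_design(design)
        st = init_state(ws, PriorConfig(n_factors=2), 0)
        st.Lambda = np.zeros_like(st.Lambda)
        st.beta = np.zeros_like(st.beta)
        rng = np.random.default_rng(13)
        update_factors(st, ws, PriorConfig(n_factors=2), rng)
        assert abs(st.H.mean()) < 0.05
        assert np.isclose(st.H.std(), 1.0, atol=0.05)

    def test_scalar_factor_conditional(self):
        """One factor, one column, known sigma2: eta | rest is the scalar
        normal-normal posterior."""
        design = lognormal_design(1, 1, seed=14)
        ws = SamplerWorkspace.from_design(design)
        y, lam, s2 = 2.0, 0.8, 0.25
        design.Y.values[0, 0] = y
        ws2 = SamplerWorkspace.from_design(design)
        st = init_state(ws2, PriorConfig(n_factors=1), 0)
        st.beta = np.zeros_like(st.beta)
        st.Lambda = np.array([[lam]])
        st.sigma2 = np.array([s2])
        rng = np.random.default_rng(15)
        draws = []
        for _ in range(20_000):
            s = st.copy()
            s.psi = np.full_like(s.psi, 1e8)  # pin loadings so only H moves
            prec = 1 + lam**2 / s2
            update_factors(s, ws2, PriorConfig(n_factors=1), rng)
            draws.append(s.H[0, 0])
        prec = 1 + lam**2 / s2
        expect_mean = (lam * y / s2) / prec
        assert np.isclose(np.mean(draws), expect_mean, atol=0.02)
        assert np.isclose(np.var(draws), 1 / prec, rtol=0.05)

    def test_shrinkage_multipliers_increase_in_prior_expectation(self):
        pr = PriorConfig(n_factors=4)
        tau_mean = np.cumprod(pr.delta_prior_means())
        assert np.all(np.diff(tau_mean) > 0)


class TestChain:
    def test_retention_bookkeeping(self, small_design):
        s = run_mcmc(small_design, PriorConfig(n_factors=1),
                     chains=2, iterations=53, burn_in=13, thin=7, seed=0)
        assert s.n_draws_per_chain == (53 - 13) // 7
        assert s.n_total == 2 * s.n_draws_per_chain

    def test_thin_one_burn_zero_retains_everything(self, small_design):
        s = run_mcmc(small_design, PriorConfig(n_factors=1),
                     chains=1, iterations=20, burn_in=0, thin=1, seed=0)
        assert s.n_draws_per_chain == 20

    def test_intercept_only_posterior_mean_matches_sample_mean(self):
        rng = np.random.default_rng(16)
        design = lognormal_design(200, 1, seed=16)
        y = rng.normal(1.3, 0.7, size=200)
        design.Y.values[:, 0] = y
        s = run_mcmc(design, PriorConfig(n_factors=0, gamma_scale=10.0),
                     chains=2, iterations=2000, burn_in=500, thin=1, seed=17)
        b0 = s.stacked("beta")[:, 0, 0]
        mcse = b0.std() / np.sqrt(200)  # generous ESS guess
        assert abs(b0.mean() - y.mean()) < 3 * max(mcse, y.std() / np.sqrt(200))

    def test_masking_equals_deleting_unobserved_values(self, small_tables):
        """Chains must be bit-identical whatever garbage sits in unobserved
        cells: missing data are marginalized, never read."""
        from jstdm.design import build_design

        ab, traits, cov = small_tables
        d1 = build_design(ab, traits, cov)
        d2 = build_design(ab, traits, cov)
        d2.Y.values = np.where(d2.Y.observed, d2.Y.values, 999.0)
        s1 = run_mcmc(d1, PriorConfig(n_factors=2), chains=1, iterations=30, burn_in=0, thin=1, seed=5)
        s2 = run_mcmc(d2, PriorConfig(n_factors=2), chains=1, iterations=30, burn_in=0, thin=1, seed=5)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.Lambda, s2.Lambda)

    def test_same_seed_reproduces_chain(self, small_design):
        a = run_mcmc(small_design, PriorConfig(n_factors=1), chains=2,
                     iterations=25, burn_in=5, thin=2, seed=9)
        b = run_mcmc(small_design, PriorConfig(n_factors=1), chains=2,
                     iterations=25, burn_in=5, thin=2, seed=9)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_invalid_settings_rejected(self, small_design):
        with pytest.raises(ValueError):
            run_mcmc(small_design, iterations=10, burn_in=10)
        with pytest.raises(ValueError):
            run_mcmc(small_design, iterations=10, burn_in=0, thin=0)


class TestDiagnostics:
    def test_identical_chains_give_unit_psrf(self):
        """Duplicating one well-mixed chain across chain slots leaves no
        between-chain variance, so the split-chain PSRF sits at 1."""
        rng = np.random.default_rng(40)
        one = rng.standard_normal((1, 400, 2, 2))
        from jstdm.sampler import PosteriorSampleSet

        ss = PosteriorSampleSet(
            beta=np.repeat(one, 2, axis=0), gamma=np.repeat(one, 2, axis=0),
            V=np.repeat(one, 2, axis=0), Lambda=np.zeros((2, 400, 0, 2)),
            sigma2=np.abs(one[:, :, 0]), H=None,
        )
        d = convergence_diagnostics(ss, include_omega=False)
        assert np.allclose(d["rhat"], 1.0, atol=0.02)

    def test_iid_draws_psrf_near_one(self):
        rng = np.random.default_rng(18)
        s = type("S", (), {})()
        fake = rng.standard_normal((4, 250, 2, 3))
        from jstdm.sampler import PosteriorSampleSet

        ss = PosteriorSampleSet(
            beta=fake, gamma=fake[:, :, :, :2], V=fake[:, :, :2, :2],
            Lambda=np.zeros((4, 250, 0, 3)), sigma2=np.abs(fake[:, :, 0]), H=None,
        )
        d = convergence_diagnostics(ss, include_omega=False)
        assert np.all(d["rhat"].to_numpy() < 1.05)
        assert np.all(d["rhat"].to_numpy() > 0.98)

    def test_divergent_chain_flagged(self):
        rng = np.random.default_rng(19)
        arr = rng.standard_normal((2, 200, 1, 1))
        arr[1] += 5.0
        from jstdm.sampler import PosteriorSampleSet

        ss = PosteriorSampleSet(
            beta=arr, gamma=arr, V=arr, Lambda=np.zeros((2, 200, 0, 1)),
            sigma2=np.abs(arr[:, :, 0]), H=None,
        )
        d = convergence_diagnostics(ss, include_omega=False)
        assert np.all(d.loc[d.block == "beta", "rhat"] > 1.1)

    def test_single_chain_errors(self, small_fit):
        import copy

        s = copy.copy(small_fit)
        s.beta = small_fit.beta[:1]
        with pytest.raises(ValueError, match="2 chains"):
            convergence_diagnostics(s)
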