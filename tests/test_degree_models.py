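"""MLE fitting, KS distance, likelihood-ratio selection of degree models."""

import numpy as np
import pytest
from scipy import integrate

from odflow import degree_models as dm
from odflow import synthetic
from odflow.errors import ContractViolationError, InvalidConfigError

K_MIN = 1000.0


@pytest.fixture(scope="module")
def se_samples():
    """1e5 draws from the stretched exponential at the taxi in-degree fit."""
    return synthetic.sample_degree_values(
        "stretched_exponential", {"beta": 0.708, "lam": 4.138e-5}, K_MIN,
        100_000, seed=3)


class TestUpperGamma:
    @pytest.mark.parametrize("a", [-2.3, -1.0, -0.4, 0.0, 0.7, 2.0])
    @pytest.mark.parametrize("x", [0.006, 0.1, 1.5])
    def test_against_quadrature(self, a, x):
        oracle, _ = integrate.quad(lambda t: t ** (a - 1) * np.exp(-t), x, np.inf)
        assert dm.upper_gamma(a, x) == pytest.approx(oracle, rel=1e-8)


class TestStretchedExponentialFit:
    def test_beta_fixed_at_one_gives_closed_form_rate(self, se_samples):
        fit = dm.fit_degree_model(se_samples, K_MIN, "stretched_exponential",
                                  fixed={"beta": 1.0})
        assert fit.params["lam"] == pytest.approx(1.0 / (se_samples.mean() - K_MIN))

    def test_profile_mle_matches_grid_search_oracle(self):
        k = synthetic.sample_degree_values(
            "stretched_exponential", {"beta": 0.7, "lam": 5e-5}, K_MIN,
            100_000, seed=41)
        fit = dm.fit_degree_model(k, K_MIN, "stretched_exponential")
        # independent coarse oracle: profile log-likelihood on a beta grid
        betas = np.arange(0.6, 0.8001, 0.002)
        lls = []
        sum_log = np.sum(np.log(k))
        for b in betas:
            lam = k.size / np.sum(k ** b - K_MIN ** b)
            lls.append(k.size * np.log(b * lam) + (b - 1) * sum_log - k.size)
        beta_grid = betas[int(np.argmax(lls))]
        assert abs(fit.params["beta"] - beta_grid) <= 0.002
        assert abs(fit.params["beta"] - 0.7) < 0.02

    def test_mle_error_shrinks_with_sample_size(self):
        errs = []
        for n in (1000, 100_000):
            k = synthetic.sample_degree_values(
                "stretched_exponential", {"beta": 0.7, "lam": 5e-5}, K_MIN, n,
                seed=13)
            fit = dm.fit_degree_model(k, K_MIN, "stretched_exponential")
            errs.append(abs(fit.params["beta"] - 0.7))
        assert errs[-1] < errs[0]


class TestPowerlawCutoffFit:
    def test_loglik_agrees_with_direct_sum(self, se_samples):
        k = se_samples[:5000]
        fit = dm.fit_degree_model(k, K_MIN, "powerlaw_cutoff")
        g, lam = fit.params["gamma"], fit.params["lam"]
        norm, _ = integrate.quad(lambda t: t ** -g * np.exp(-lam * t), K_MIN, np.inf)
        direct = np.sum(-g * np.log(k) - lam * k) - k.size * np.log(norm)
        assert fit.log_likelihood == pytest.approx(direct, rel=1e-6)

    def test_rate_recovery_with_exponent_fixed(self):
        lam_true = 6.086e-6
        k = synthetic.sample_degree_values(
            "powerlaw_cutoff", {"gamma": 1.0, "lam": lam_true}, K_MIN,
            20_000, seed=7)
        fit = dm.fit_degree_model(k, K_MIN, "powerlaw_cutoff", fixed={"gamma": 1.0})
        assert fit.params["lam"] == pytest.approx(lam_true, rel=0.1)

    def test_vanishing_rate_approaches_pure_power_law(self, se_samples):
        k = se_samples[:2000]
        gamma = 1.7
        ll_pl = np.sum(dm._logpdf("powerlaw", k, {"gamma": gamma}, K_MIN))
        ll_ec = np.sum(dm._logpdf("powerlaw_cutoff", k,
                                  {"gamma": gamma, "lam": 1e-13}, K_MIN))
        assert ll_ec == pytest.approx(ll_pl, abs=0.01)


class TestNormalization:
    @pytest.mark.parametrize("model", dm.MODELS)
    def test_fitted_density_integrates_to_one(self, model, se_samples):
        fit = dm.fit_degree_model(se_samples[:5000], K_MIN, model)
        # substitute u = ln k so both localized and heavy-tailed densities
        # are integrable to infinity by adaptive quadrature

        def integrand(u):
            with np.errstate(over="ignore", invalid="ignore"):
                val = float(fit.logpdf(np.exp(u))) + u
            return np.exp(val) if np.isfinite(val) else 0.0

        total, err = integrate.quad(integrand, np.log(K_MIN), np.inf, limit=400)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestKSDistance:
    def test_hand_computed_exponential_example(self):
        # three points {1,2,3} against CDF 1 - e^-k: the sup over the six
        # step candidates is |F(1) - 0| = 0.63212
        fit = dm.DegreeFitResult(model_id="exponential", params={"lam": 1.0},
                                 k_min=0.0, log_likelihood=0.0, ks=0.0, n=3)
        assert dm.ks_distance([1.0, 2.0, 3.0], fit) == pytest.approx(
            1 - np.exp(-1), abs=1e-12)

    def test_ks_shrinks_when_model_is_true(self):
        vals = []
        for n in (1000, 100_000):
            k = synthetic.sample_degree_values(
                "stretched_exponential", {"beta": 0.7, "lam": 5e-5}, K_MIN, n,
                seed=21)
            vals.append(dm.fit_degree_model(k, K_MIN, "stretched_exponential").ks)
        assert vals[-1] < vals[0]

    def test_samples_below_kmin_rejected(self):
        with pytest.raises(ContractViolationError):
            dm.fit_degree_model(np.linspace(500, 2000, 100), K_MIN, "exponential")


class TestLikelihoodRatio:
    def test_identical_fits_are_inconclusive(self, se_samples):
        fit = dm.fit_degree_model(se_samples[:1000], K_MIN, "exponential")
        R, norm, p = dm.loglik_ratio(fit, fit, se_samples[:1000])
        assert R == 0.0 and norm == 0.0 and p == 1.0

    def test_exponential_data_favors_exponential_over_power_law(self):
        k = synthetic.sample_degree_values("exponential", {"lam": 1e-4}, K_MIN,
                                           10_000, seed=17)
        fit_exp = dm.fit_degree_model(k, K_MIN, "exponential")
        fit_pl = dm.fit_degree_model(k, K_MIN, "powerlaw")
        R, norm, p = dm.loglik_ratio(fit_exp, fit_pl, k)
        # oracle: the ratio is exactly the difference of summed log-densities
        direct = float(np.sum(fit_exp.logpdf(k)) - np.sum(fit_pl.logpdf(k)))
        assert R == pytest.approx(direct, rel=1e-12)
        assert R > 0 and p < 0.01


class TestModelSelection:
    def test_se_generated_samples_rank_se_first(self, se_samples):
        ranked = dm.select_best(se_samples, K_MIN)
        assert ranked[0].model_id == "stretched_exponential"

    def test_single_candidate_returned(self, se_samples):
        ranked = dm.select_best(se_samples[:200], K_MIN, models=("exponential",))
        assert [f.model_id for f in ranked] == ["exponential"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidConfigError):
            dm.select_best(np.full(10, 2000.0), K_MIN)
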