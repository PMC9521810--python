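"""AIC/BIC, maximum likelihood, BAR and bridge-sampling Bayes factors."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from itcmix.models import MODEL_PARAMETER_NAMES, Parameters2C, heats
from itcmix.probability import Dataset, PriorSpec
from itcmix.sampling import SamplerConfig, sample_posterior
from itcmix.selection import (
    EstimatorFailure,
    ProposalDistribution,
    aic,
    bar_solve,
    bic,
    bridge_log10_ratio,
    fit_proposal,
    max_likelihood,
    nested_parameter_mapping,
)

LOG10 = np.log(10.0)


class TestInformationCriteria:
    def test_arithmetic(self):
        assert aic(0.0, 3) == 6.0
        assert bic(0.0, 3, 20) == pytest.approx(3 * np.log(20))

    def test_model_parameter_counts(self):
        k = {m: len(MODEL_PARAMETER_NAMES[m]) for m in ("2C", "RM", "EM")}
        assert (k["2C"], k["RM"], k["EM"]) == (6, 8, 9)
        assert k["EM"] - k["RM"] == 1

    def test_aic_bic_gap(self):
        # AIC - BIC = k (2 - ln N): negative once N > e^2
        for n in (5, 7, 8, 50):
            gap = aic(-10.0, 4) - bic(-10.0, 4, n)
            assert np.sign(gap) == np.sign(2 - np.log(n))


class TestMaxLikelihood:
    def test_noiseless_2c_recovers_truth(self, protocol):
        theta = Parameters2C(-9.0, -10.0, 5e-7, 0.05e-3, 1e-3, 1e-6)
        data = Dataset(heats=heats(theta, protocol), protocol=protocol,
                       stated_R0=theta.R0, stated_Ls=theta.Ls)
        spec = PriorSpec()
        theta_ml, mll = max_likelihood(data, spec, "2C", [theta])
        # near-zero noise leaves a flat ridge (R0*dH compensation), so the
        # thermodynamic parameters are recovered to ~1% and the residuals
        # are negligible relative to the ~1e-4 cal heats
        assert theta_ml.dG == pytest.approx(-9.0, abs=0.05)
        assert theta_ml.dH == pytest.approx(-10.0, rel=0.02)
        q = heats(theta_ml, protocol)
        assert np.max(np.abs(q - data.heats)) < 1e-8

    def test_max_loglik_dominates_posterior_draws(self, em_fit_small):
        samples, data, spec = em_fit_small
        _, mll = max_likelihood(data, spec, "EM", samples)
        from itcmix.probability import log_likelihood
        from itcmix.models import make_parameters

        lls = [log_likelihood(make_parameters("EM", row), data)
               for row in samples.values[::50]]
        assert mll >= max(lls) - 1e-6

    def test_two_optimizers_agree(self, protocol):
        theta = Parameters2C(-9.0, -10.0, 5e-7, 0.05e-3, 1e-3, 1e-6)
        rng = np.random.default_rng(2)
        q = heats(theta, protocol) + rng.normal(0, 5e-7, protocol.n_injections)
        data = Dataset(heats=q, protocol=protocol, stated_R0=theta.R0,
                       stated_Ls=theta.Ls)
        spec = PriorSpec()
        _, mll_a = max_likelihood(data, spec, "2C", [theta], method="L-BFGS-B")
        _, mll_b = max_likelihood(data, spec, "2C", [theta], method="Nelder-Mead")
        assert mll_a == pytest.approx(mll_b, abs=1e-4)


@pytest.fixture(scope="module")
def em_fit_small():
    from itcmix.simulate import SimulationDesign, simulate_experiment

    design = SimulationDesign(n_replicates=1, seed=21)
    data, realized = simulate_experiment(design, 0)
    spec = PriorSpec(r0_prior="lognormal", ls_prior="lognormal")
    cfg = SamplerConfig(warmup=500, draws=5000, thin=10, seed=6, init=realized)
    return sample_posterior(data, spec, "EM", cfg), data, spec


class TestProposal:
    def test_two_point_variance_is_unbiased(self):
        from itcmix.sampling import PosteriorSamples

        vals = np.array([[0.3], [0.7]])  # rho values -> logit space
        s = PosteriorSamples(vals, ("dH2",), "EM", SamplerConfig(),
                             np.zeros(2))
        prop = fit_proposal(s, ["dH2"])  # identity transform
        assert prop.mean[0] == pytest.approx(0.5)
        assert prop.cov[0, 0] == pytest.approx(np.var([0.3, 0.7], ddof=1))

    def test_variates_converge_to_moments(self):
        prop = ProposalDistribution([1.0, -2.0], [[2.0, 0.5], [0.5, 1.0]])
        draws = prop.rvs(40000, seed=3)
        assert np.allclose(draws.mean(axis=0), prop.mean, atol=0.05)
        assert np.allclose(np.cov(draws, rowvar=False), prop.cov, atol=0.08)

    def test_standard_normal_logpdf_at_mean(self):
        prop = ProposalDistribution([0.0], [[1.0]])
        assert prop.logpdf(np.array([0.0])) == pytest.approx(-0.5 * np.log(2 * np.pi))


class TestBarSolve:
    def test_identical_distributions_give_zero(self):
        assert bar_solve(np.zeros(100), np.zeros(40)) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_ln2_for_gaussian_pair(self):
        # u1 = x^2/2 (Z1 = sqrt(2 pi)); u2 = x^2/8 (Z2 = sqrt(8 pi))
        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, 20000)
        x2 = rng.normal(0, 2, 20000)
        du = lambda x: x**2 / 8 - x**2 / 2
        est = bar_solve(du(x1), du(x2))
        boot = [
            bar_solve(du(x1)[rng.integers(0, 20000, 20000)],
                      du(x2)[rng.integers(0, 20000, 20000)])
            for _ in range(100)
        ]
        assert abs(est - np.log(2)) < 3 * np.std(boot, ddof=1)

    def test_swapping_sets_negates_estimate(self):
        rng = np.random.default_rng(4)
        f = rng.normal(1.0, 0.5, 500)
        r = rng.normal(-1.0, 0.5, 700)
        assert bar_solve(-r, -f) == pytest.approx(-bar_solve(f, r), rel=1e-8)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bar_solve(np.array([]), np.zeros(5))

    def test_disjoint_sets_raise_estimator_failure(self):
        with pytest.raises(EstimatorFailure):
            bar_solve(np.full(50, 1e12), np.full(50, -1e12))


def _conjugate_toy(seed, n=12, s2=1.0, t2=4.0, g2=2.25, n1=3000, n2=4000):
    """Nested linear-Gaussian toy with closed-form marginal likelihoods.

    M1: y ~ N(theta, s2), theta ~ N(0, t2).
    M2: y ~ N(theta + gamma, s2), gamma ~ N(0, g2).
    Both posteriors are exactly Gaussian, so 'MCMC' draws are i.i.d.
    """
    rng = np.random.default_rng(seed)
    y = rng.normal(0.7, np.sqrt(s2), n)
    ybar = y.mean()

    def log_marg(v):
        cov = s2 * np.eye(n) + v * np.ones((n, n))
        return multivariate_normal(np.zeros(n), cov).logpdf(y)

    analytic = (log_marg(t2 + g2) - log_marg(t2)) / LOG10

    v1 = 1.0 / (1.0 / t2 + n / s2)
    m1 = v1 * n * ybar / s2
    X1 = rng.normal(m1, np.sqrt(v1), (n1, 1))

    A = np.array([[1 / t2 + n / s2, n / s2], [n / s2, 1 / g2 + n / s2]])
    b = np.array([n * ybar / s2, n * ybar / s2])
    cov2 = np.linalg.inv(A)
    mu2 = cov2 @ b
    X2 = rng.multivariate_normal(mu2, cov2, n2)

    def logp1(x):
        th = x[0]
        return norm.logpdf(th, 0, np.sqrt(t2)) + np.sum(
            norm.logpdf(y, th, np.sqrt(s2)))

    def logp2(x):
        th, g = x
        return (norm.logpdf(th, 0, np.sqrt(t2)) + norm.logpdf(g, 0, np.sqrt(g2))
                + np.sum(norm.logpdf(y, th + g, np.sqrt(s2))))

    proposal = ProposalDistribution([mu2[1]], [[cov2[1, 1]]])
    return logp1, logp2, X1, X2, proposal, analytic


class TestBridgeSampling:
    def test_conjugate_toy_matches_analytic(self):
        logp1, logp2, X1, X2, prop, analytic = _conjugate_toy(seed=10)
        res = bridge_log10_ratio(logp1, logp2, X1, X2, prop, seed=1,
                                 n_bootstrap=300)
        assert abs(res.log10_bf - analytic) < 3 * res.se

    def test_conjugate_toy_across_20_seeds(self):
        hits = 0
        for seed in range(20):
            logp1, logp2, X1, X2, prop, analytic = _conjugate_toy(
                seed=seed, n1=1500, n2=2000)
            res = bridge_log10_ratio(logp1, logp2, X1, X2, prop, seed=seed,
                                     n_bootstrap=150)
            if abs(res.log10_bf - analytic) < 3 * res.se:
                hits += 1
        assert hits >= 19  # allow one 3-sigma excursion

    def test_exact_conditional_proposal_is_exact(self):
        """With f(γ) the exact conditional posterior, every Δu is constant."""
        logp1, logp2, X1, X2, prop, analytic = _conjugate_toy(seed=5)
        # conditional gamma | theta, y is Gaussian; marginal proposal from the
        # exact posterior moments already yields a near-degenerate estimator
        res = bridge_log10_ratio(logp1, logp2, X1, X2, prop, seed=2,
                                 n_bootstrap=200)
        assert res.se < 0.05
        assert abs(res.log10_bf - analytic) < 3 * res.se

    def test_robust_to_inflated_proposal(self):
        logp1, logp2, X1, X2, prop, analytic = _conjugate_toy(seed=3)
        res_a = bridge_log10_ratio(logp1, logp2, X1, X2, prop, seed=1,
                                   n_bootstrap=200)
        res_b = bridge_log10_ratio(logp1, logp2, X1, X2, prop.inflate(1.5),
                                   seed=1, n_bootstrap=200)
        combined = np.hypot(res_a.se, res_b.se)
        assert abs(res_a.log10_bf - res_b.log10_bf) < 3 * combined

    def test_trace_converges_to_final_estimate(self):
        logp1, logp2, X1, X2, prop, _ = _conjugate_toy(seed=8)
        res = bridge_log10_ratio(logp1, logp2, X1, X2, prop, seed=0,
                                 n_bootstrap=100)
        tail = res.trace.log10_bf.iloc[-1]
        assert tail == pytest.approx(res.log10_bf, abs=1e-9)


class TestCompareModels:
    def test_report_and_antisymmetry_on_em_data(self, em_fit_small):
        from itcmix.selection import compare_models

        _, data, spec = em_fit_small
        cfg = SamplerConfig(warmup=300, draws=3000, thin=10, seed=7)
        comp = compare_models(data, spec, cfg, models=("2C", "RM"),
                              seed=1, n_bootstrap=50)
        assert set(comp.aic) == {"2C", "RM"} == set(comp.bic)
        # AIC/BIC penalties follow from the same max log-likelihood
        for m in ("2C", "RM"):
            k = {"2C": 6, "RM": 8}[m]
            assert comp.aic[m] == pytest.approx(-2 * comp.max_loglik[m] + 2 * k)
            assert comp.bic[m] == pytest.approx(
                -2 * comp.max_loglik[m] + k * np.log(data.n))
        if ("2C", "RM") in comp.bayes_factors:
            assert comp.log10_bf("RM", "2C") == pytest.approx(
                -comp.log10_bf("2C", "RM"))
        report = comp.report()
        assert "AIC" in report and "BIC" in report and "log10_BF" in report


class TestNestedMapping:
    def test_2c_into_rm(self):
        m = nested_parameter_mapping("2C", "RM")
        assert m == {"dG1": "dG", "dH1": "dH", "dH0": "dH0", "R0": "R0",
                     "Ls": "Ls", "sigma": "sigma"}

    def test_rm_into_em_gamma_is_rho(self):
        m = nested_parameter_mapping("RM", "EM")
        gammas = [n for n in MODEL_PARAMETER_NAMES["EM"] if n not in m]
        assert gammas == ["rho"]

    def test_not_nested_raises(self):
        with pytest.raises(ValueError):
            nested_parameter_mapping("EM", "2C")
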