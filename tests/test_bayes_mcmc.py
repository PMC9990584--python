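import numpy as np
import pytest
from scipy import optimize

from jpcrayleigh import (
    CensoringScheme,
    GammaPriors,
    JointParams,
    MCMCConfig,
    PosteriorDraws,
    PowerRayleighParams,
    bayes_point_estimates,
    credible_intervals,
    fit_joint_mle,
    generate_jpc_sample,
    joint_loglik,
    log_conditional_kernel,
    log_posterior_kernel,
    run_mh_gibbs,
)
from jpcrayleigh.bayes_mcmc import linex_estimate

PRIORS = GammaPriors()  # a = 0.02, b = 2 throughout
THETA = JointParams(PowerRayleighParams(0.7, 1.2), PowerRayleighParams(0.9, 1.4))


def _chain(draws: np.ndarray) -> PosteriorDraws:
    return PosteriorDraws(draws=draws, acceptance_rate=np.full(4, 0.5),
                          initial_state=THETA)


class TestKernels:
    def test_kernel_differences_match_loglik_plus_prior(self, sample_3040):
        other = JointParams(PowerRayleighParams(0.5, 2.0), PowerRayleighParams(1.1, 0.8))
        diff_kernel = (log_posterior_kernel(THETA, sample_3040, PRIORS)
                       - log_posterior_kernel(other, sample_3040, PRIORS))
        diff_direct = (joint_loglik(THETA, sample_3040) + PRIORS.logpdf(THETA.as_array())
                       - joint_loglik(other, sample_3040) - PRIORS.logpdf(other.as_array()))
        assert diff_kernel == pytest.approx(diff_direct, abs=1e-10)
        assert log_posterior_kernel(np.array([-1.0, 1, 1, 1]), sample_3040, PRIORS) == -np.inf

    @pytest.mark.parametrize("index", [0, 1, 2, 3])
    def test_conditional_kernel_is_joint_restriction(self, sample_3040, index):
        """Each full-conditional kernel differs from the joint kernel,
        restricted to that coordinate, by an additive constant."""
        base = THETA.as_array()
        grid = np.linspace(0.5, 1.6, 7) * base[index]
        diffs = []
        for v in grid:
            vec = base.copy()
            vec[index] = v
            diffs.append(log_posterior_kernel(vec, sample_3040, PRIORS)
                         - log_conditional_kernel(index, v, base, sample_3040, PRIORS))
        assert np.max(diffs) - np.min(diffs) < 1e-8

    def test_flat_prior_kernel_maximizer_is_the_mle(self):
        sc = CensoringScheme(m=25, n=25, r=50, R=(0,) * 50)
        smp = generate_jpc_sample(THETA.pop1, THETA.pop2, sc, seed=21)
        mle = fit_joint_mle(smp).estimate.as_array()
        flat = GammaPriors(a=np.ones(4), b=np.full(4, 1e-9))
        res = optimize.minimize(
            lambda v: -log_posterior_kernel(np.exp(v), smp, flat),
            x0=np.log(mle * 1.3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert np.allclose(np.exp(res.x), mle, rtol=1e-4)


@pytest.fixture(scope="module")
def fit_and_chain(sample_3040):
    fit = fit_joint_mle(sample_3040)
    cfg = MCMCConfig(n_iter=4000, burn_in=400, seed=77, proposal_sd=fit.se)
    draws = run_mh_gibbs(sample_3040, PRIORS, fit.estimate, cfg)
    return fit, cfg, draws


class TestSampler:
    def test_seed_determinism(self, sample_3040, fit_and_chain):
        fit, cfg, draws = fit_and_chain
        again = run_mh_gibbs(sample_3040, PRIORS, fit.estimate, cfg)
        assert np.array_equal(draws.draws, again.draws)

    def test_burn_in_drops_exact_prefix(self, sample_3040, fit_and_chain):
        fit, cfg, draws = fit_and_chain
        full = run_mh_gibbs(sample_3040, PRIORS, fit.estimate,
                            MCMCConfig(n_iter=cfg.n_iter, burn_in=0, seed=cfg.seed,
                                       proposal_sd=cfg.proposal_sd))
        assert np.array_equal(full.draws[cfg.burn_in:], draws.draws)

    def test_retained_draws_positive_and_rates_moderate(self, fit_and_chain):
        _, _, draws = fit_and_chain
        assert np.all(draws.draws > 0)
        assert np.all((draws.acceptance_rate > 0.05) & (draws.acceptance_rate < 0.95))

    def test_posterior_concentrates_near_truth(self, truth1, scheme_3040):
        smp = generate_jpc_sample(truth1.pop1, truth1.pop2, scheme_3040, seed=2)
        fit = fit_joint_mle(smp)
        cfg = MCMCConfig(n_iter=4000, burn_in=400, seed=5, proposal_sd=fit.se)
        draws = run_mh_gibbs(smp, PRIORS, fit.estimate, cfg)
        mean = draws.draws.mean(axis=0)
        sd = draws.draws.std(axis=0)
        assert np.all(np.abs(mean - truth1.as_array()) < 4 * sd)

    def test_posterior_moments_match_quadrature_of_the_kernel(self, sample_3040):
        """The likelihood factorizes over populations, so the (alpha1, beta1)
        posterior marginal can be integrated on a 2-D grid and compared with
        the chain — a dual-route check of sampler correctness."""
        fit = fit_joint_mle(sample_3040)
        cfg = MCMCConfig(n_iter=12000, burn_in=1000, seed=30, proposal_sd=fit.se)
        draws = run_mh_gibbs(sample_3040, PRIORS, fit.estimate, cfg)
        mle, se = fit.estimate.as_array(), fit.se
        a_grid = np.linspace(max(1e-3, mle[0] - 6 * se[0]), mle[0] + 6 * se[0], 241)
        b_grid = np.linspace(max(1e-3, mle[2] - 6 * se[2]), mle[2] + 6 * se[2], 241)
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        logk = np.empty_like(A)
        base = mle.copy()
        for i, a in enumerate(a_grid):
            for jj, b in enumerate(b_grid):
                vec = base.copy()
                vec[0], vec[2] = a, b
                logk[i, jj] = log_posterior_kernel(vec, sample_3040, PRIORS)
        w = np.exp(logk - logk.max())
        w /= w.sum()
        mean_a = float((w * A).sum())
        chain_a = draws.draws[:, 0]
        nb = 20
        batches = chain_a[: nb * (chain_a.size // nb)].reshape(nb, -1).mean(axis=1)
        mc_se = batches.std(ddof=1) / np.sqrt(nb)
        assert abs(chain_a.mean() - mean_a) < 3 * mc_se + 1e-3

    def test_missing_proposal_scales_rejected(self, sample_3040):
        with pytest.raises(ValueError, match="proposal_sd"):
            run_mh_gibbs(sample_3040, PRIORS, THETA, MCMCConfig(n_iter=10, burn_in=0))


class TestPointEstimates:
    def test_linex_hand_value(self):
        # -log((e^-1 + e^-2 + e^-3)/3) = -log(0.5530014/3)
        draws = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        est = linex_estimate(draws, 1.0)
        assert est[0] == pytest.approx(1.6910063, abs=1e-6)

    def test_degenerate_chain_returns_the_point(self):
        draws = np.full((200, 4), 3.7)
        summ = bayes_point_estimates(_chain(draws), c_list=(-2.0, 0.5, 2.0))
        assert np.allclose(summ.se_estimate, 3.7)
        for est in summ.linex_estimates.values():
            assert np.allclose(est, 3.7, atol=1e-10)

    def test_jensen_ordering_in_c(self):
        rng = np.random.default_rng(6)
        draws = rng.gamma(4.0, 0.5, size=(500, 4))
        lo = linex_estimate(draws, 2.0)
        hi = linex_estimate(draws, -2.0)
        se = draws.mean(axis=0)
        assert np.all(hi >= se) and np.all(se >= lo)

    def test_linex_converges_to_posterior_mean(self):
        rng = np.random.default_rng(7)
        draws = rng.gamma(3.0, 0.8, size=(1000, 4))
        se = draws.mean(axis=0)
        near = linex_estimate(draws, 1e-4)
        assert np.all(np.abs(near - se) < 1e-3 * np.abs(se))

    def test_linex_relative_continuity_on_real_data_chain(self):
        """On the published joint-censored record — whose honest fit has
        very large scale estimates — the LINEX(1e-4) estimate still agrees
        with the posterior mean to 0.1% relative."""
        from jpcrayleigh import MCMCConfig, fit_joint_mle, load_fixture, run_mh_gibbs

        sample, _ = load_fixture("jpc_application").payload
        fit = fit_joint_mle(sample)
        draws = run_mh_gibbs(sample, PRIORS, fit.estimate,
                             MCMCConfig(n_iter=2000, burn_in=200, seed=1,
                                        proposal_sd=fit.se))
        se = draws.draws.mean(axis=0)
        near = linex_estimate(draws.draws, 1e-4)
        assert np.all(np.abs(near - se) < 1e-3 * np.abs(se))

    def test_c_zero_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            linex_estimate(np.ones((10, 4)), 0.0)


class TestCredibleIntervals:
    def test_full_level_returns_range(self):
        rng = np.random.default_rng(8)
        draws = rng.gamma(2.0, 1.0, size=(400, 4))
        ci = credible_intervals(_chain(draws), level=1.0)
        for j, name in enumerate(ci.bounds):
            assert ci[name][0] == pytest.approx(draws[:, j].min())
            assert ci[name][1] == pytest.approx(draws[:, j].max())

    def test_symmetric_chain_gives_symmetric_interval(self):
        rng = np.random.default_rng(9)
        half = np.abs(rng.normal(size=(2000, 4)))
        draws = 5.0 + np.concatenate([half, -half])
        ci = credible_intervals(_chain(draws), level=0.9)
        for name in ci.bounds:
            lo, hi = ci[name]
            assert (5.0 - lo) == pytest.approx(hi - 5.0, abs=1e-9)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            credible_intervals(_chain(np.ones((50, 4))))

    def test_hpd_no_wider_than_equal_tailed(self):
        rng = np.random.default_rng(10)
        draws = rng.gamma(2.0, 1.0, size=(2000, 4))
        eq = credible_intervals(_chain(draws), level=0.95)
        hpd = credible_intervals(_chain(draws), level=0.95, method="hpd")
        assert np.all(hpd.lengths() <= eq.lengths() + 1e-9)
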