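"""Priors, likelihood aggregation, log posterior and the DEzs sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcrange import calibration as cal
from dcrange import synthetic
from .conftest import make_zstack, neutral_theta, uniform_state


class TestPriors:
    def test_slope_outside_truncation_is_impossible(self):
        priors = cal.default_priors()
        theta = neutral_theta().to_array()
        theta[1] = 6.0  # slope beyond [-5, 5]
        assert cal.log_prior(theta, priors) == -np.inf

    def test_truncated_normal_density_matches_scipy(self):
        p = cal.Prior(0.0, 1.0, -5.0, 5.0)
        for x in (-4.2, -1.0, 0.0, 0.7, 4.9):
            expected = stats.truncnorm.logpdf(x, -5.0, 5.0, loc=0.0, scale=1.0)
            assert p.logpdf(x) == pytest.approx(expected, abs=1e-10)

    def test_prior_set_density_is_sum_of_marginals(self):
        priors = cal.default_priors()
        rng = np.random.default_rng(0)
        theta = priors.sample(rng, 1)[0]
        total = sum(p.logpdf(theta[i]) for i, p in enumerate(priors.priors.values()))
        assert priors.logpdf(theta) == pytest.approx(total, abs=1e-9)

    def test_density_at_prior_means_is_finite(self):
        priors = cal.default_priors()
        means = np.array([p.mean for p in priors.priors.values()])
        assert np.isfinite(priors.logpdf(means))


class TestTransform:
    def test_round_trip(self):
        tr = cal.ParamTransform.for_model()
        theta = neutral_theta(b=0.05, p_e=0.4, d_mean=2.5, sigma=33.0).to_array()
        assert np.allclose(tr.to_natural(tr.to_sampling(theta)), theta, atol=1e-12)

    def test_jacobian_matches_numerical_derivative(self):
        tr = cal.ParamTransform.for_model()
        u = tr.to_sampling(neutral_theta(b=0.05, p_e=0.4, d_mean=2.5, sigma=33.0).to_array())
        eps = 1e-6
        log_det = 0.0
        for j in range(len(u)):
            up, um = u.copy(), u.copy()
            up[j] += eps
            um[j] -= eps
            deriv = (tr.to_natural(up)[j] - tr.to_natural(um)[j]) / (2 * eps)
            log_det += np.log(abs(deriv))
        assert tr.log_jacobian(u) == pytest.approx(log_det, abs=1e-5)


class TestNbLoglik:
    def test_zero_count_zero_mean_contributes_nothing(self):
        assert cal.nb_loglik(np.array([0]), np.array([0.0]), 5.0) == pytest.approx(0.0, abs=1e-5)

    def test_matches_log_gamma_closed_form(self):
        from scipy.special import gammaln
        y, mu, sigma = 3, 2.0, 5.0
        expected = (gammaln(y + sigma) - gammaln(sigma) - gammaln(y + 1)
                    + sigma * np.log(sigma / (sigma + mu)) + y * np.log(mu / (sigma + mu)))
        assert cal.nb_loglik(np.array([y]), np.array([mu]), sigma) == pytest.approx(expected, abs=1e-10)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            cal.nb_loglik(np.array([1]), np.array([1.0]), 0.0)


class TestAggregation:
    def _survey(self, rows, cols, years, counts):
        recs = []
        for s, (r, c) in enumerate(zip(rows, cols)):
            for y in years:
                recs.append({"site_id": s, "x_cell": c, "y_cell": r,
                             "year": y, "count": counts[s]})
        return pd.DataFrame(recs)

    def test_one_site_per_block_is_identity(self):
        survey = self._survey([0, 10, 20], [0, 10, 20], [2000], [3, 5, 7])
        sim = np.zeros((1, 2, 30, 30))
        sim[0, :, [0, 10, 20], [0, 10, 20]] = [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]
        y, mu = cal.aggregate_for_likelihood(sim, survey, [2000], block_size=5)
        assert sorted(y.tolist()) == [3, 5, 7]
        assert sorted(mu.tolist()) == [1.0, 2.0, 3.0]

    def test_block_sums_counts(self):
        survey = self._survey([0, 1, 2, 3], [0, 1, 2, 3], [2000], [1, 2, 3, 4])
        sim = np.zeros((1, 1, 10, 10))
        y, mu = cal.aggregate_for_likelihood(sim, survey, [2000], block_size=10)
        assert y.tolist() == [10.0]

    def test_replicate_means(self):
        survey = self._survey([0, 1], [0, 1], [2000], [2, 2])
        sim = np.zeros((1, 2, 5, 5))
        sim[0, 0, [0, 1], [0, 1]] = [2.0, 4.0]   # replicate block sum 6
        sim[0, 1, [0, 1], [0, 1]] = [3.0, 5.0]   # replicate block sum 8
        _, mu = cal.aggregate_for_likelihood(sim, survey, [2000], block_size=5)
        assert mu.tolist() == [7.0]


@pytest.fixture(scope="module")
def small_model():
    scen = synthetic.SyntheticScenario(
        nrows=12, ncols=12, first_year=2000, last_year=2005,
        n_sites=20, spinup_years=8, seed=5,
    )
    b = synthetic.generate(scen)
    model = cal.PosteriorModel(
        priors=cal.default_priors(), survey=b.survey, climate=b.climate,
        habitat=b.habitat, initial=b.truth.initial, n_reps=4, block_size=6)
    return b, model


class TestPosteriorModel:
    def test_out_of_support_short_circuits_simulator(self, small_model):
        b, model = small_model
        before = model.n_sim
        theta = b.scenario.theta_true.to_array()
        theta[1] = 7.0
        assert model.log_posterior(theta, np.random.default_rng(0)) == -np.inf
        assert model.n_sim == before

    def test_pinned_seed_is_deterministic(self, small_model):
        b, _ = small_model
        model = cal.PosteriorModel(
            priors=cal.default_priors(), survey=b.survey, climate=b.climate,
            habitat=b.habitat, initial=b.truth.initial, n_reps=3, block_size=6,
            seed_policy="fixed", fixed_seed=9)
        theta = b.scenario.theta_true.to_array()
        assert model.log_posterior(theta) == model.log_posterior(theta)

    def test_likelihood_variance_shrinks_with_replicates(self, small_model):
        b, _ = small_model
        theta = b.scenario.theta_true.to_array()

        def loglik_var(n_reps, n=25):
            model = cal.PosteriorModel(
                priors=cal.default_priors(), survey=b.survey, climate=b.climate,
                habitat=b.habitat, initial=b.truth.initial, n_reps=n_reps, block_size=6)
            rng = np.random.default_rng(123)
            return np.var([model.log_posterior(theta, rng) for _ in range(n)], ddof=1)

        v2, v16 = loglik_var(2), loglik_var(16)
        assert v16 < v2 / 2  # roughly 1/n_reps scaling, tested loosely


class TestDezs:
    def test_flat_posterior_accepts_every_de_proposal(self):
        priors = cal.PriorSet({f"x{i}": cal.Prior(0.0, 1.0) for i in range(3)})
        run = cal.dezs_sample(lambda x, rng: 0.0, priors, iterations=600,
                              n_chains=1, seed=0, snooker_prob=0.0)
        assert run.accept_rate[0] == 1.0

    def test_gaussian_target_moments(self):
        means = np.array([1.0, -2.0])
        sds = np.array([0.5, 1.5])

        def logpost(x, rng):
            z = (x - means) / sds
            return float(-0.5 * z @ z)

        priors = cal.PriorSet({"a": cal.Prior(0.0, 3.0), "b": cal.Prior(0.0, 3.0)})
        run = cal.dezs_sample(logpost, priors, n_chains=3, iterations=6000, seed=1)
        pool = run.pooled()
        assert np.allclose(pool.mean(axis=0), means, atol=0.12)
        assert np.allclose(pool.std(axis=0), sds, rtol=0.15)

    def test_archive_too_small_raises(self):
        priors = cal.PriorSet({f"x{i}": cal.Prior(0.0, 1.0) for i in range(4)})
        with pytest.raises(ValueError):
            cal.dezs_sample(lambda x, rng: 0.0, priors, iterations=100,
                            z0_factor=1, seed=0)


def _fake_run(chains):
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    return cal.McmcRun(
        samples=chains, logpost=np.zeros(chains.shape[:2]),
        names=tuple(f"p{i}" for i in range(chains.shape[2])),
        accept_rate=np.zeros(chains.shape[0]), burn_fraction=0.0,
    )


class TestGelmanRubin:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=2000)
        gr = cal.gelman_rubin(_fake_run(np.stack([c, c, c])))
        assert gr["max_psrf"] < 1.01 and gr["converged"]

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        gr = cal.gelman_rubin(_fake_run(np.stack([
            rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])))
        assert gr["max_psrf"] > 2.0 and not gr["converged"]

    def test_iid_chains_from_same_normal(self):
        rng = np.random.default_rng(2)
        gr = cal.gelman_rubin(_fake_run(rng.normal(size=(3, 5000))))
        assert gr["max_psrf"] < 1.05

    def test_short_chains_rejected(self):
        with pytest.raises(ValueError):
            cal.gelman_rubin(_fake_run(np.zeros((2, 8))))


class TestPosteriorDraws:
    def test_oversampling_draws_members_of_pool(self):
        rng = np.random.default_rng(0)
        run = _fake_run(rng.normal(size=(2, 50, 3)))
        draws = cal.posterior_draws(run, n=400, seed=1)
        pool = run.pooled()
        assert draws.shape == (400, 3)
        assert all(any(np.array_equal(d, row) for row in pool) for d in draws[:10])

    def test_marginal_means_consistent(self):
        rng = np.random.default_rng(3)
        run = _fake_run(rng.normal(2.0, 1.0, size=(3, 4000, 1)))
        draws = cal.posterior_draws(run, n=400, seed=2)
        pool_mean = run.pooled().mean()
        assert abs(draws.mean() - pool_mean) < 3 * 1.0 / np.sqrt(400)

    def test_seeded_draws_reproducible(self):
        rng = np.random.default_rng(4)
        run = _fake_run(rng.normal(size=(2, 100, 2)))
        assert np.array_equal(cal.posterior_draws(run, 50, seed=9),
                              cal.posterior_draws(run, 50, seed=9))


class TestPseudoMarginalCoverage:
    def test_dispersion_credible_intervals_cover_truth(self):
        """80% CIs for the NB dispersion cover the truth at roughly the
        nominal rate when the likelihood mean is a fresh stochastic estimate
        at every evaluation (pseudo-marginal behaviour at fixture scale)."""
        sigma_true, mu_true, n_obs = 10.0, 5.0, 300
        prior = cal.PriorSet({"sigma": cal.Prior(50.0, 50.0, 1e-6, 500.0)})
        tr = cal.ParamTransform(["log"])
        hits = 0
        repeats = 20
        for rep in range(repeats):
            data_rng = np.random.default_rng(1000 + rep)
            y = data_rng.negative_binomial(sigma_true, sigma_true / (sigma_true + mu_true), n_obs)

            def logpost(theta, rng):
                mu_hat = rng.poisson(mu_true * 40) / 40.0  # unbiased noisy mean
                return prior.logpdf(theta) + cal.nb_loglik(y, np.full(n_obs, mu_hat), theta[0])

            run = cal.dezs_sample(logpost, prior, transform=tr, n_chains=2,
                                  iterations=1500, seed=rep)
            lo, hi = np.quantile(run.pooled()[:, 0], [0.10, 0.90])
            hits += lo <= sigma_true <= hi
        # Binomial(20, 0.8): P(hits < 12) < 0.01
        assert hits >= 12
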