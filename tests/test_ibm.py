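"""Stochastic population processes: reproduction, dispersal, survival, stepping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dcrange import dcr, ibm
from dcrange.dcr import RateMaps
from dcrange.ibm import DispersalParams

from .conftest import make_zstack, neutral_theta, uniform_state


def uniform_rates(shape, rho=1.0, s_j=0.5, s_a=0.5, year=2000):
    return RateMaps(
        rho_max=np.full(shape, float(rho)),
        s_j=np.full(shape, float(s_j)),
        s_a=np.full(shape, float(s_a)),
        year=year,
    )


class TestReproduce:
    def test_no_adults_no_juveniles(self):
        shape = (4, 4)
        out = ibm.reproduce(np.zeros(shape, dtype=int), uniform_rates(shape),
                            np.full(shape, 100), 0.01, np.random.default_rng(0))
        assert not out.any()

    def test_unsuitable_cells_produce_nothing(self):
        shape = (3, 3)
        adults = np.full(shape, 5)
        h = np.zeros(shape)
        out = ibm.reproduce(adults, uniform_rates(shape, rho=2.0), h, 0.01,
                            np.random.default_rng(1))
        assert not out.any()

    def test_monte_carlo_mean_matches_analytic(self):
        """Replicate mean within 3 SE of n * rho(n) for the Poisson cohort."""
        n, rho_max, b, h = 12, 1.8, 0.02, 50.0
        shape = (1, 1)
        reps = 10_000
        adults = np.full((reps,) + shape, n)
        out = ibm.reproduce(adults, uniform_rates(shape, rho=rho_max),
                            np.full(shape, h), b, np.random.default_rng(2))
        expected = n * rho_max * np.exp(-n * b * 100 / h)
        se = out.std() / np.sqrt(reps)
        assert abs(out.mean() - expected) < 3 * se

    def test_per_individual_mode_matches_per_cell_mean(self):
        n, rho_max = 7, 1.3
        shape = (1, 1)
        reps = 4000
        adults = np.full((reps,) + shape, n)
        rates = uniform_rates(shape, rho=rho_max)
        h = np.full(shape, 100.0)
        rng = np.random.default_rng(3)
        cell = ibm.reproduce(adults, rates, h, 1e-9, rng)
        indiv = ibm.reproduce(adults, rates, h, 1e-9, rng, per_individual=True)
        se = np.hypot(cell.std(), indiv.std()) / np.sqrt(reps)
        assert abs(cell.mean() - indiv.mean()) < 3 * se


class TestDisperse:
    def test_no_emigration_identity(self):
        rng = np.random.default_rng(0)
        juv = rng.integers(0, 5, size=(6, 6))
        h = np.full((6, 6), 100)
        settled, deaths = ibm.disperse(juv, h, DispersalParams(0.0, 2.0), rng)
        assert np.array_equal(settled, juv) and deaths == 0

    def test_isolated_cell_long_kernel_kills_emigrants(self):
        h = np.zeros((21, 21), dtype=int)
        h[10, 10] = 100
        juv = np.zeros_like(h)
        juv[10, 10] = 2000
        settled, deaths = ibm.disperse(
            juv, h, DispersalParams(1.0, 50.0), np.random.default_rng(1))
        assert settled.sum() + deaths == 2000
        assert deaths > 0.95 * 2000  # nearly all emigrants die

    @given(seed=st.integers(0, 10_000))
    def test_individual_conservation(self, seed):
        rng = np.random.default_rng(seed)
        h = (rng.random((8, 8)) < 0.6).astype(int) * 100
        juv = rng.integers(0, 6, size=(3, 8, 8)) * (h > 0)
        dp = DispersalParams(rng.uniform(0, 1), rng.uniform(0.2, 5.0))
        settled, deaths = ibm.disperse(juv, h, dp, rng)
        assert settled.sum() + deaths.sum() == juv.sum()
        assert not settled[:, h == 0].any()

    def test_settlement_prefers_destination_then_neighbours(self):
        # natal cell at centre; destination ring unsuitable but its neighbours
        # partially suitable -> settlers end up only on suitable cells
        rng = np.random.default_rng(5)
        h = np.zeros((15, 15), dtype=int)
        h[7, 7] = 100
        h[5, :] = 100
        juv = np.zeros_like(h)
        juv[7, 7] = 5000
        settled, deaths = ibm.disperse(juv, h, DispersalParams(1.0, 2.0), rng)
        assert settled.sum() + deaths == 5000
        assert not settled[h == 0].any()
        assert settled[5, :].sum() > 0


class TestKernel:
    def test_exponential_mean_and_uniform_direction(self):
        dp = DispersalParams(1.0, 3.5)
        dist, angle = ibm.draw_kernel(200_000, dp, np.random.default_rng(7))
        assert abs(dist.mean() - 3.5) / 3.5 < 0.01
        hist, _ = np.histogram(angle, bins=24, range=(0, 2 * np.pi))
        from scipy.stats import chisquare
        assert chisquare(hist).pvalue > 0.01


class TestSurvival:
    def test_certain_survival_adds_stages(self):
        shape = (5, 5)
        rng = np.random.default_rng(0)
        adults = rng.integers(0, 10, shape)
        juv = rng.integers(0, 10, shape)
        new_a, new_j = ibm.survive_and_transition(
            adults, juv, uniform_rates(shape, s_j=1.0, s_a=1.0), rng)
        assert np.array_equal(new_a, adults + juv) and not new_j.any()

    def test_certain_death_extinction(self):
        shape = (4, 4)
        rng = np.random.default_rng(1)
        new_a, _ = ibm.survive_and_transition(
            np.full(shape, 9), np.full(shape, 4),
            uniform_rates(shape, s_j=0.0, s_a=0.0), rng)
        assert not new_a.any()

    def test_binomial_means(self):
        shape = (1, 1)
        reps = 10_000
        adults = np.full((reps,) + shape, 20)
        juv = np.full((reps,) + shape, 30)
        new_a, _ = ibm.survive_and_transition(
            adults, juv, uniform_rates(shape, s_j=0.35, s_a=0.7),
            np.random.default_rng(2))
        expected = 20 * 0.7 + 30 * 0.35
        se = new_a.std() / np.sqrt(reps)
        assert abs(new_a.mean() - expected) < 3 * se

    def test_survivors_never_exceed_counts(self):
        rng = np.random.default_rng(3)
        adults = rng.integers(0, 50, (10, 6, 6))
        juv = rng.integers(0, 50, (10, 6, 6))
        new_a, _ = ibm.survive_and_transition(
            adults, juv, uniform_rates((6, 6), s_j=0.9, s_a=0.9), rng)
        assert (new_a <= adults + juv).all()


class TestStepYear:
    def test_empty_state_stays_empty(self):
        shape = (5, 5)
        out = ibm.step_year(np.zeros(shape, dtype=int), uniform_rates(shape),
                            np.full(shape, 100), 0.01, DispersalParams(0.3, 2.0),
                            np.random.default_rng(0))
        assert not out.any()

    def test_one_step_mean_field(self):
        """With p_e=0 and uniform rates, E[adults'] = n (s_a + s_j rho(n))."""
        shape = (1, 1)
        n, rho_max, b, s_j, s_a = 40, 1.2, 0.001, 0.5, 0.6
        reps = 20_000
        adults = np.full((reps,) + shape, n)
        out = ibm.step_year(adults, uniform_rates(shape, rho_max, s_j, s_a),
                            np.full(shape, 100.0), b, DispersalParams(0.0, 1.0),
                            np.random.default_rng(1))
        rho = rho_max * np.exp(-n * b)
        expected = n * (s_a + s_j * rho)
        se = out.std() / np.sqrt(reps)
        assert abs(out.mean() - expected) < 3 * se

    def test_process_order_contract(self):
        """step_year is exactly reproduce -> disperse -> survive with shared streams."""
        shape = (7, 7)
        rng = np.random.default_rng(4)
        h = (rng.random(shape) < 0.7).astype(int) * 60
        adults = rng.integers(0, 8, shape) * (h > 0)
        rates = uniform_rates(shape, rho=1.5, s_j=0.4, s_a=0.7)
        dp = DispersalParams(0.4, 1.5)
        rngs = tuple(ibm.stream(99, 0, p) for p in (1, 2, 3))
        stepped = ibm.step_year(adults, rates, h, 0.02, dp, rngs)
        rngs2 = tuple(ibm.stream(99, 0, p) for p in (1, 2, 3))
        juv = ibm.reproduce(adults, rates, h, 0.02, rngs2[0])
        settled, _ = ibm.disperse(juv, h, dp, rngs2[1])
        manual, _ = ibm.survive_and_transition(adults, settled, rates, rngs2[2])
        assert np.array_equal(stepped, manual)

    def test_accounting_info(self):
        shape = (6, 6)
        rng = np.random.default_rng(5)
        h = np.full(shape, 100)
        adults = rng.integers(0, 10, shape)
        _, info = ibm.step_year(adults, uniform_rates(shape, rho=2.0), h, 0.01,
                                DispersalParams(0.5, 1.0), rng, return_info=True)
        assert info["settled"] + info["dispersal_deaths"] == info["produced"]


class TestSimulate:
    def test_identical_rep_seeds_identical_replicates(self, tiny_bundle):
        b = tiny_bundle
        sim = ibm.simulate(b.scenario.theta_true, b.climate, b.habitat,
                           b.truth.initial, n_reps=2, rep_seeds=[123, 123])
        assert np.array_equal(sim[:, 0], sim[:, 1])
        sim2 = ibm.simulate(b.scenario.theta_true, b.climate, b.habitat,
                            b.truth.initial, n_reps=2, rep_seeds=[123, 456])
        assert not np.array_equal(sim2[:, 0], sim2[:, 1])

    def test_same_seed_bit_identical(self, tiny_bundle):
        b = tiny_bundle
        args = (b.scenario.theta_true, b.climate, b.habitat, b.truth.initial)
        s1 = ibm.simulate(*args, n_reps=3, seed=7)
        s2 = ibm.simulate(*args, n_reps=3, seed=7)
        assert np.array_equal(s1, s2)

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_deterministic_limits(self, engine):
        """Rates driven to {0, 1}: the trajectory is computable by hand."""
        stack = make_zstack(years=[2000, 2001, 2002], shape=(5, 5))
        h = np.full((5, 5), 100)
        init = uniform_state((5, 5), 4)
        # certain survival, zero fecundity: constant adult population
        theta = neutral_theta(fec_0=-60.0, sj_0=60.0, sa_0=60.0)
        sim = ibm.simulate(theta, stack, h, init, n_reps=2, seed=1, engine=engine)
        assert (sim == 4).all()
        # certain death: immediate extinction
        theta0 = neutral_theta(fec_0=-60.0, sj_0=-60.0, sa_0=-60.0)
        sim0 = ibm.simulate(theta0, stack, h, init, n_reps=2, seed=1, engine=engine)
        assert not sim0.any()

    def test_support_never_grows_without_emigration(self):
        stack = make_zstack(years=list(range(2000, 2008)), shape=(9, 9))
        h = np.full((9, 9), 100)
        adults = np.zeros((9, 9), dtype=np.int64)
        adults[4, 4] = 30
        adults[2, 6] = 30
        init = ibm.PopulationState(adults=adults, juveniles=np.zeros_like(adults))
        theta = neutral_theta(fec_0=0.5, sj_0=0.5, sa_0=0.5, p_e=0.0)
        sim = ibm.simulate(theta, stack, h, init, n_reps=5, seed=3)
        occupied0 = adults > 0
        assert not sim[:, :, ~occupied0].any()

    def test_monotone_in_adult_survival_under_common_random_numbers(self):
        """Raising s_a pointwise (same Bernoulli draws) cannot lose adults."""
        shape = (6, 6)
        rng_state = np.random.default_rng(11)
        h = np.full(shape, 100)
        adults = rng_state.integers(0, 10, shape)
        juv = rng_state.integers(0, 10, shape)
        lo = uniform_rates(shape, s_j=0.5, s_a=0.4)
        hi = uniform_rates(shape, s_j=0.5, s_a=0.8)
        a_lo, _ = ibm.survive_and_transition(adults, juv, lo, ibm.stream(5, 0),
                                             per_individual=True)
        a_hi, _ = ibm.survive_and_transition(adults, juv, hi, ibm.stream(5, 0),
                                             per_individual=True)
        assert (a_hi >= a_lo).all()

    def test_engines_agree_in_distribution(self, tiny_bundle):
        b = tiny_bundle
        args = (b.scenario.theta_true, b.climate, b.habitat, b.truth.initial)
        tot_f = ibm.simulate(*args, n_reps=150, seed=5, engine="fast").sum(axis=(2, 3))
        tot_r = ibm.simulate(*args, n_reps=150, seed=5, engine="reference").sum(axis=(2, 3))
        for yi in (0, len(tot_f) - 1):
            se = np.hypot(tot_f[yi].std(), tot_r[yi].std()) / np.sqrt(150)
            assert abs(tot_f[yi].mean() - tot_r[yi].mean()) < 4 * se

    def test_grid_mismatch_raises(self, tiny_bundle):
        b = tiny_bundle
        with pytest.raises(ValueError):
            ibm.simulate(b.scenario.theta_true, b.climate, np.ones((3, 3)),
                         b.truth.initial)
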