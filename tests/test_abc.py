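"""ABC rejection, population Monte Carlo, regression adjustment, posteriors."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from zipfbias import (
    ABCConfig,
    DomainError,
    ParticlePopulation,
    PowerLawModel,
    abc_pmc,
    abc_regression,
    abc_rejection,
    map_estimate,
    sample_counts,
)
from zipfbias.abc_engine import posterior_from_population
from zipfbias.rankfreq import RankFrequencyCounts, mean_log_count


def _obs(lam=1.5, N=500, seed=0):
    return sample_counts(PowerLawModel(lam), N, seed).counts


SMALL = dict(n_particles=60, n_generations=4, max_draws_per_generation=50_000)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"survival_fraction": 0.0},
        {"survival_fraction": 1.0},
        {"prior_lambda": (2.0, 1.5)},
        {"prior_lambda": (0.9, 3.0)},   # unbounded W needs lambda > 1
        {"prior_q": (-1, 5)},
        {"n_particles": 1},
    ])
    def test_invalid_settings_rejected(self, bad):
        with pytest.raises(DomainError):
            ABCConfig(**bad)


class TestRejection:
    def test_infinite_tolerance_recovers_prior(self):
        # with epsilon = inf accepted exponents are draws from the uniform
        # prior; KS should not reject in at least 19 of 20 seeded runs
        obs = _obs()
        lo, hi = 1.001, 3.0
        failures = 0
        for seed in range(20):
            cfg = ABCConfig(n_particles=100, seed=seed, prior_lambda=(lo, hi))
            pop = abc_rejection(obs, "zipf", cfg, epsilon=math.inf)
            p = kstest(pop.particles[:, 0], "uniform",
                       args=(lo, hi - lo)).pvalue
            failures += p < 0.001
        assert failures <= 1

    def test_deterministic(self):
        obs = _obs()
        cfg = ABCConfig(n_particles=50, seed=7)
        a = abc_rejection(obs, "zipf", cfg, epsilon=math.inf)
        b = abc_rejection(obs, "zipf", cfg, epsilon=math.inf)
        assert np.array_equal(a.particles, b.particles)
        assert np.array_equal(a.distances, b.distances)

    def test_parameter_recovery_at_small_tolerance(self):
        # pilot run sets epsilon at a low quantile of the prior-predictive
        # distances; the accepted posterior mean should sit near the truth
        obs = _obs(lam=1.5, N=10_000, seed=1)
        pilot = abc_rejection(obs, "zipf",
                              ABCConfig(n_particles=800, seed=2,
                                        max_draws_per_generation=10_000),
                              epsilon=math.inf)
        eps = float(np.quantile(pilot.distances, 0.05))
        cfg = ABCConfig(n_particles=100, seed=3,
                        max_draws_per_generation=50_000)
        pop = abc_rejection(obs, "zipf", cfg, epsilon=eps)
        assert float(pop.particles[:, 0].mean()) == pytest.approx(1.5, abs=0.1)

    def test_cap_error(self):
        obs = _obs()
        cfg = ABCConfig(n_particles=50, seed=0, max_draws_per_generation=10)
        with pytest.raises(Exception, match="simulations"):
            abc_rejection(obs, "zipf", cfg, epsilon=1e-12)


class TestPMC:
    def test_tolerances_non_increasing_and_deterministic(self):
        obs = _obs(N=1000, seed=4)
        cfg = ABCConfig(seed=5, **SMALL)
        schedule = []
        pop, post = abc_pmc(obs, "zipf", cfg,
                            progress=lambda r: schedule.append(r["tolerance"]))
        assert all(schedule[i + 1] <= schedule[i]
                   for i in range(len(schedule) - 1))
        pop2, post2 = abc_pmc(obs, "zipf", cfg)
        assert np.array_equal(pop.particles, pop2.particles)
        assert post.map_estimate == post2.map_estimate

    def test_population_invariants(self):
        obs = _obs(N=1000, seed=4)
        pop, _ = abc_pmc(obs, "zipf", ABCConfig(seed=6, **SMALL))
        assert pop.n == SMALL["n_particles"]
        assert pop.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pop.distances < pop.tolerance)

    def test_posterior_integrates_to_one(self):
        obs = _obs(N=1000, seed=4)
        cfg = ABCConfig(seed=6, **SMALL)
        _, post = abc_pmc(obs, "zipf", cfg)
        area = np.trapezoid(post.density, post.support)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_credible_interval_brackets_map(self):
        obs = _obs(N=1000, seed=4)
        _, post = abc_pmc(obs, "zipf", ABCConfig(seed=8, **SMALL))
        lo, hi = post.credible_interval(0.95)
        assert lo < post.map_estimate < hi

    def test_zm_with_q_pinned_to_zero_matches_zipf(self):
        # 2-parameter machinery restricted to q = 0 must agree with the
        # 1-parameter run up to Monte-Carlo error
        obs = _obs(lam=1.4, N=2000, seed=9)
        cfg1 = ABCConfig(seed=10, **SMALL)
        cfg2 = ABCConfig(seed=10, prior_q=(0, 0), **SMALL)
        _, post1 = abc_pmc(obs, "zipf", cfg1)
        _, post2 = abc_pmc(obs, "zipf_mandelbrot", cfg2)
        lam2, q2 = post2.map_estimate
        assert q2 == 0
        assert lam2 == pytest.approx(post1.map_estimate, abs=0.15)

    def test_two_parameter_posterior_integrates_to_one(self):
        obs = sample_counts(
            __import__("zipfbias").ZipfMandelbrotModel(lambda_=1.3, q=2),
            2000, 11).counts
        cfg = ABCConfig(seed=12, prior_q=(0, 8), **SMALL)
        _, post = abc_pmc(obs, "zipf_mandelbrot", cfg)
        grid, qs = post.support
        total = np.trapezoid(post.density, grid, axis=1).sum()
        assert total == pytest.approx(1.0, abs=1e-6)
        assert post.q_marginal().sum() == pytest.approx(1.0, abs=1e-9)


class TestRegression:
    def test_summary_statistic_values(self):
        assert mean_log_count(
            RankFrequencyCounts(np.array([1, 1, 1]))) == 0.0
        assert mean_log_count(
            RankFrequencyCounts(np.array([7, 7]))) == pytest.approx(
                math.log(7), rel=1e-12)

    def test_parameter_recovery(self):
        # point estimates across seeded runs should cluster on the truth
        errs = []
        for seed in range(10):
            obs = sample_counts(PowerLawModel(1.5), 10_000, 100 + seed).counts
            cfg = ABCConfig(seed=seed, regression_draws=1000)
            post = abc_regression(obs, "zipf", cfg)
            errs.append(post.point_estimate - 1.5)
        assert abs(np.mean(errs)) < 0.1

    def test_deterministic(self):
        obs = _obs(N=2000, seed=13)
        cfg = ABCConfig(seed=14, regression_draws=300)
        a = abc_regression(obs, "zipf", cfg)
        b = abc_regression(obs, "zipf", cfg)
        assert a.point_estimate == b.point_estimate

    def test_two_parameter_family_rejected(self):
        with pytest.raises(DomainError):
            abc_regression(_obs(), "zipf_mandelbrot", ABCConfig())


class TestMapEstimate:
    def test_identical_particles(self):
        pop = ParticlePopulation(
            particles=np.full((20, 1), 1.3), weights=np.full(20, 0.05),
            distances=np.zeros(20), tolerance=1.0, generation=0)
        assert map_estimate(pop) == pytest.approx(1.3, abs=0.002)

    def test_concentrated_weight(self):
        parts = np.array([[1.2], [1.8]])
        pop = ParticlePopulation(
            particles=parts, weights=np.array([0.99, 0.01]),
            distances=np.zeros(2), tolerance=1.0, generation=0)
        cfg = ABCConfig(prior_lambda=(1.001, 3.0))
        assert map_estimate(pop, cfg) == pytest.approx(1.2, abs=0.01)

    def test_matches_direct_grid_evaluation(self, rng):
        # two weighted clusters: the returned mode must equal the argmax of
        # a directly evaluated weighted Gaussian KDE on the same grid
        from scipy.stats import gaussian_kde
        lam = np.concatenate([rng.normal(1.3, 0.02, 80),
                              rng.normal(2.1, 0.05, 40)])
        w = np.concatenate([np.full(80, 2.0), np.full(40, 1.0)])
        w = w / w.sum()
        pop = ParticlePopulation(
            particles=lam[:, None], weights=w,
            distances=np.zeros(120), tolerance=1.0, generation=0)
        cfg = ABCConfig(prior_lambda=(1.001, 3.0))
        got = map_estimate(pop, cfg)
        grid = np.linspace(1.001, 3.0, 2000)
        dens = gaussian_kde(lam, weights=w, bw_method="silverman")(grid)
        assert got == pytest.approx(grid[int(np.argmax(dens))], abs=0.002)
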