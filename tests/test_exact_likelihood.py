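"""Permutation-sum likelihood, permanents, and the exact MLEs."""

import itertools
import math

import numpy as np
import pytest

from zipfbias import (
    BoundaryError,
    DomainError,
    PermanentSizeError,
    PowerLawModel,
    RankMapping,
    full_loglik,
    full_loglik_gradient,
    full_score,
    leading_term_loglik,
    log_permanent,
    mle_full,
    mle_leading_finite,
    mle_leading_unbounded,
    permutation_term_loglik,
)
from zipfbias.exact_likelihood import LikelihoodMatrix, log_permanent_of_values

from conftest import random_counts


def brute_force_log_permanent(A: np.ndarray) -> float:
    """Independent oracle: permanent by direct sum over permutations."""
    W = A.shape[0]
    total = math.fsum(
        math.prod(A[i, p[i]] for i in range(W))
        for p in itertools.permutations(range(W))
    )
    return math.log(total)


def brute_force_full_loglik(counts, lam, W) -> float:
    """Independent oracle: the permutation-sum likelihood term by term."""
    p = (np.arange(1, W + 1) ** -float(lam))
    p = p / p.sum()
    padded = np.zeros(W)
    padded[: len(counts)] = counts
    total = math.fsum(
        math.prod(p[r] ** padded[perm[r]] for r in range(W))
        for perm in itertools.permutations(range(W))
    )
    return math.log(total)


class TestPermanent:
    def test_identity_matrix(self):
        assert log_permanent_of_values(np.eye(3)) == pytest.approx(0.0, abs=1e-14)

    def test_all_ones_counts_permutations(self):
        assert math.exp(log_permanent_of_values(np.ones((4, 4)))) == \
            pytest.approx(24.0, rel=1e-12)

    @pytest.mark.parametrize("engine", ["naive", "ryser"])
    def test_engines_match_brute_force(self, engine, rng):
        for _ in range(10):
            A = rng.random((6, 6)) * 0.999 + 0.001
            got = log_permanent_of_values(A, engine=engine)
            assert got == pytest.approx(brute_force_log_permanent(A), rel=1e-11)

    def test_engines_agree_beyond_naive_range(self, rng):
        A = rng.random((9, 9)) * 0.999 + 0.001
        assert log_permanent_of_values(A, "ryser") == pytest.approx(
            log_permanent_of_values(A, "naive"), rel=1e-9)

    def test_log_scale_entries_survive_underflow(self):
        # entries like p^n with n ~ 1e4 underflow doubles; log-domain input
        # must still give a finite result
        logA = np.full((3, 3), -5000.0)
        got = log_permanent(logA)
        assert got == pytest.approx(-15000.0 + math.log(6), rel=1e-12)

    def test_size_cap(self):
        with pytest.raises(PermanentSizeError):
            log_permanent(np.zeros((26, 26)))

    def test_zero_row_gives_zero_permanent(self):
        logA = np.zeros((3, 3))
        logA[1, :] = -np.inf
        assert log_permanent(logA, engine="ryser") == -np.inf


class TestLeadingTerm:
    def test_single_event_probability_one(self):
        assert leading_term_loglik([5], 1.3, 1) == pytest.approx(0.0, abs=1e-14)

    def test_direct_arithmetic(self):
        expected = 3 * math.log(6 / 11) + 2 * math.log(3 / 11) + math.log(2 / 11)
        assert leading_term_loglik([3, 2, 1], 1.0, 3) == pytest.approx(
            expected, rel=1e-12)

    def test_equals_identity_permutation_term(self, small_counts):
        model = PowerLawModel(lambda_=1.4, W=6)
        lead = leading_term_loglik(small_counts, 1.4, 6)
        ident = permutation_term_loglik(small_counts, RankMapping.identity(6),
                                        model)
        assert lead == pytest.approx(ident, rel=1e-12)

    def test_unbounded_uses_zeta(self):
        from scipy.special import zeta
        got = leading_term_loglik([4, 1], 2.0, np.inf)
        expected = -5 * math.log(zeta(2.0)) - 2.0 * math.log(2)
        assert got == pytest.approx(expected, rel=1e-12)


class TestPermutationTerm:
    def test_example_mapping(self):
        # n = [8,6,3,2,1,1] with s = [2,1,5,3,4,6] gives
        # p1^6 p2^8 p3^1 p4^3 p5^2 p6^1
        model = PowerLawModel(lambda_=1.0, W=6)
        s = RankMapping(np.array([2, 1, 5, 3, 4, 6]))
        got = permutation_term_loglik([8, 6, 3, 2, 1, 1], s, model)
        p = model.pmf(np.arange(1, 7))
        expected = math.log(p[0]**6 * p[1]**8 * p[2]**1 * p[3]**3
                            * p[4]**2 * p[5]**1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_uniform_model_is_permutation_invariant(self, rng):
        model = PowerLawModel(lambda_=0.0, W=5)
        counts = [4, 3, 2, 1, 1]
        expected = 11 * math.log(1 / 5)
        for _ in range(5):
            s = RankMapping(rng.permutation(np.arange(1, 6)))
            assert permutation_term_loglik(counts, s, model) == pytest.approx(
                expected, rel=1e-12)

    def test_rejects_non_bijection(self):
        model = PowerLawModel(lambda_=1.0, W=3)
        with pytest.raises(DomainError):
            permutation_term_loglik([2, 1], np.array([1, 1, 3]), model)


class TestFullLoglik:
    def test_single_event(self):
        for lam in (0.2, 1.0, 3.0):
            assert full_loglik([7], lam, 1) == pytest.approx(0.0, abs=1e-12)

    def test_two_event_hand_sum(self):
        # counts [3,1], W=2, lambda=1: L = p1^3 p2 + p1 p2^3, p1=2/3, p2=1/3
        expected = math.log((2 / 3) ** 3 * (1 / 3) + (2 / 3) * (1 / 3) ** 3)
        assert full_loglik([3, 1], 1.0, 2) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(8):
            c = random_counts(rng, W_max=6)
            lam = float(rng.uniform(0.3, 2.5))
            W = c.W_obs + int(rng.integers(0, 2))  # sometimes pad a zero
            assert full_loglik(c, lam, W) == pytest.approx(
                brute_force_full_loglik(c.counts, lam, W), rel=1e-9)

    def test_dominates_leading_term(self, small_counts):
        for lam in np.linspace(0.5, 3.0, 26):
            assert full_loglik(small_counts, float(lam), 6) >= \
                leading_term_loglik(small_counts, float(lam), 6) - 1e-12


class TestGradient:
    def test_single_event_is_zero(self):
        assert full_loglik_gradient([7], 1.3, 1) == 0.0

    def test_matches_finite_difference(self):
        h = 1e-6
        fd = (math.exp(full_loglik([3, 2, 1], 1.2 + h, 3))
              - math.exp(full_loglik([3, 2, 1], 1.2 - h, 3))) / (2 * h)
        assert full_loglik_gradient([3, 2, 1], 1.2, 3) == pytest.approx(
            fd, rel=1e-4)

    def test_score_vanishes_at_mle(self, small_counts):
        lam_hat = mle_full(small_counts, 6)
        assert abs(full_score(small_counts, lam_hat, 6)) < 1e-3

    def test_score_sign_change_brackets_mle(self, small_counts):
        lam_hat = mle_full(small_counts, 6)
        assert full_score(small_counts, lam_hat - 0.05, 6) > 0
        assert full_score(small_counts, lam_hat + 0.05, 6) < 0


class TestEstimators:
    def test_leading_finite_demo_value(self, small_counts):
        assert round(mle_leading_finite(small_counts, 6), 2) == 1.27

    def test_full_demo_value(self, small_counts):
        assert round(mle_full(small_counts, 6), 2) == 1.16

    def test_full_below_leading_on_bunched_tail(self, small_counts):
        assert mle_full(small_counts, 6) < mle_leading_finite(small_counts, 6)

    def test_leading_finite_uniform_counts_hit_zero(self):
        # equal counts fit a uniform distribution: boundary at lambda = 0,
        # confirmed by a grid search oracle
        counts = [5, 5, 5, 5]
        grid = np.linspace(0, 3, 301)
        vals = [leading_term_loglik(counts, float(l), 4) for l in grid]
        assert grid[int(np.argmax(vals))] == 0.0
        with pytest.warns(RuntimeWarning):
            assert mle_leading_finite(counts, 4) == 0.0

    def test_single_event_data_rejected(self):
        with pytest.raises(BoundaryError):
            mle_leading_unbounded([10])
        with pytest.raises(BoundaryError):
            mle_leading_finite([7], 1)
        with pytest.raises(BoundaryError):
            mle_full([7], 1)

    def test_unbounded_mle_on_known_ranks_matches_grid_oracle(self):
        from scipy.special import zeta
        counts = np.array([50, 20, 10, 5, 5, 3, 2, 1])
        lam_hat = mle_leading_unbounded(counts)
        grid = np.linspace(1.01, 3.5, 2000)
        ranks = np.arange(1, 9)
        ll = [-96 * math.log(zeta(l)) - l * np.sum(counts * np.log(ranks))
              for l in grid]
        assert lam_hat == pytest.approx(grid[int(np.argmax(ll))], abs=2e-3)

    def test_likelihood_curves_have_unique_interior_maxima(self, small_counts):
        grid = np.linspace(0.5, 2.5, 101)
        lead = np.array([leading_term_loglik(small_counts, float(l), 6)
                         for l in grid])
        full = np.array([full_loglik(small_counts, float(l), 6) for l in grid])
        for curve, mle in ((lead, 1.27), (full, 1.16)):
            peaks = np.flatnonzero((curve[1:-1] > curve[:-2])
                                   & (curve[1:-1] > curve[2:])) + 1
            assert peaks.size == 1
            assert grid[peaks[0]] == pytest.approx(mle, abs=0.02)

    def test_w_defaults_to_observed(self, small_counts):
        assert mle_full(small_counts) == pytest.approx(
            mle_full(small_counts, 6), abs=1e-9)


class TestLikelihoodMatrix:
    def test_permanent_equals_enumerated_likelihood(self, rng):
        c = random_counts(rng, W_max=5)
        lam = 1.1
        model = PowerLawModel(lambda_=lam, W=c.W_obs)
        m = LikelihoodMatrix.build(c, model, c.W_obs)
        assert log_permanent(m) == pytest.approx(
            brute_force_full_loglik(c.counts, lam, c.W_obs), rel=1e-10)

    def test_rejects_w_below_observed(self, small_counts):
        model = PowerLawModel(lambda_=1.0, W=3)
        with pytest.raises(DomainError):
            LikelihoodMatrix.build(small_counts, model, 3)
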