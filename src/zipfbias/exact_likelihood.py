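"""Exact likelihoods for rank-frequency data, with and without the
rank-identification assumption.

For counts ``n`` observed under a ranked probability model with W events,
the probability of the data must account for every way the W probability
ranks could have produced the W empirical ranks:

    L(lambda | n) = sum over permutations s of  prod_r p(r)^{n(s(r))}

The prevailing estimators keep only the identity-permutation term
(empirical rank = probability rank) — the "leading term". That term is a
valid likelihood only when ranks are known a priori; for rank-frequency
data it induces a positive bias in the fitted exponent, strongest for
exponents near 1.

The full sum equals the permanent of the W x W matrix a[i][j] =
p(i)^{n(j)}, so it inherits the permanent's #P-hardness; this module
computes it exactly up to W = MAX_PERMANENT_W events via Ryser's
inclusion-exclusion algorithm (O(W 2^W)) or brute-force enumeration
(O(W!), cross-check engine), both carried out in log space.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp

from ._errors import (BoundaryError, DomainError, InconsistencyError,
                      PermanentSizeError)
from .models import (SizeLike, UNBOUNDED, ZipfMandelbrotModel, PowerLawModel,
                     is_unbounded, normalizer, normalizer_derivative)
from .rankfreq import RankFrequencyCounts, RankMapping

__all__ = [
    "MAX_PERMANENT_W",
    "LikelihoodMatrix",
    "log_permanent",
    "leading_term_loglik",
    "permutation_term_loglik",
    "full_loglik",
    "full_loglik_gradient",
    "full_score",
    "mle_leading_unbounded",
    "mle_leading_finite",
    "mle_full",
]

#: Hard cap on exact permanent computation; cost doubles with every event.
MAX_PERMANENT_W = 25

#: Largest W for which the O(W!) enumeration engine is the default.
_NAIVE_DEFAULT_MAX = 8

#: Relative magnitude below which Ryser's alternating sum is considered to
#: have cancelled away more than ~6 significant digits.
_RYSER_CANCEL_TOL = 1e-6

LAMBDA_MAX_DEFAULT = 4.0
_LAMBDA_MIN_UNBOUNDED = 1.0 + 1e-9
_OPT_XATOL = 1e-6


def _as_counts_array(counts) -> np.ndarray:
    if isinstance(counts, RankFrequencyCounts):
        return counts.counts
    return RankFrequencyCounts(np.asarray(counts)).counts


# ---------------------------------------------------------------------------
# Likelihood matrix and permanents


@dataclass(frozen=True)
class LikelihoodMatrix:
    """Log-domain W x W matrix whose permanent is the full likelihood.

    ``log_entries[i, j] = n_j * log p(i+1)`` — row index is probability
    rank, column index is empirical rank (the permanent is invariant under
    transposition). Entries are held in logs because p^n underflows double
    precision for realistic counts.
    """

    log_entries: np.ndarray

    @classmethod
    def build(cls, counts, model: ZipfMandelbrotModel, W: int) -> "LikelihoodMatrix":
        c = _as_counts_array(counts)
        if W < c.size:
            raise DomainError(f"W={W} smaller than W_obs={c.size}")
        padded = np.zeros(W, dtype=np.float64)
        padded[: c.size] = c
        log_p = np.asarray(model.log_pmf(np.arange(1, W + 1)), dtype=np.float64)
        return cls(padded[None, :] * log_p[:, None])

    @property
    def W(self) -> int:
        return self.log_entries.shape[0]


def _log_permanent_naive(logA: np.ndarray) -> float:
    """log perm(A) by log-sum-exp over all W! permutation terms."""
    W = logA.shape[0]
    idx = np.fromiter(itertools.chain.from_iterable(itertools.permutations(range(W))),
                      dtype=np.int64).reshape(-1, W)
    terms = logA[np.arange(W)[None, :], idx].sum(axis=1)
    return float(logsumexp(terms))


def _ryser_signed_sum(rows_exp: np.ndarray) -> tuple[float, float]:
    """Gray-code Ryser inclusion-exclusion on a matrix of non-negative
    entries. Returns (signed sum, largest absolute partial term) so the
    caller can detect catastrophic cancellation.

    perm(A) = (-1)^W * sum_{S subset of columns} (-1)^{|S|} prod_i sum_{j in S} a_ij
    """
    W = rows_exp.shape[0]
    row_sums = np.zeros(W, dtype=np.float64)
    total = 0.0
    comp = 0.0  # Kahan compensation
    max_term = 0.0
    gray = 0
    for k in range(1, 1 << W):
        bit = (k & -k).bit_length() - 1
        gray_new = k ^ (k >> 1)
        if gray_new > gray:
            row_sums += rows_exp[:, bit]
        else:
            row_sums -= rows_exp[:, bit]
        gray = gray_new
        popcount = gray.bit_count()
        term = math.prod(row_sums.tolist())
        if (W - popcount) & 1:
            term = -term
        max_term = max(max_term, abs(term))
        # compensated accumulation
        y = term - comp
        t = total + y
        comp = (t - total) - y
        total = t
    return total, max_term


def _log_permanent_ryser(logA: np.ndarray) -> float:
    W = logA.shape[0]
    # per-row scaling keeps entries in (0, 1]
    row_max = logA.max(axis=1)
    finite = np.isfinite(row_max)
    if not finite.all():
        return -math.inf  # a whole row is zero => permanent is zero
    scaled = np.exp(logA - row_max[:, None])
    total, max_term = _ryser_signed_sum(scaled)
    if total <= 0.0 or (max_term > 0 and total / max_term < _RYSER_CANCEL_TOL):
        warnings.warn(
            "Ryser alternating sum lost more than 6 significant digits; "
            "recomputing the permanent in arbitrary precision",
            RuntimeWarning, stacklevel=3)
        total = _ryser_mpmath(scaled)
        if total <= 0:
            return -math.inf
        return float(mpmath.log(total)) + float(row_max.sum())
    return math.log(total) + float(row_max.sum())


def _ryser_mpmath(rows_exp: np.ndarray):
    """High-precision Ryser fallback for cancellation-prone matrices."""
    W = rows_exp.shape[0]
    with mpmath.workdps(30 + 3 * W):
        A = [[mpmath.mpf(float(v)) for v in row] for row in rows_exp]
        row_sums = [mpmath.mpf(0)] * W
        total = mpmath.mpf(0)
        gray = 0
        for k in range(1, 1 << W):
            bit = (k & -k).bit_length() - 1
            gray_new = k ^ (k >> 1)
            sign = 1 if gray_new > gray else -1
            for i in range(W):
                row_sums[i] += sign * A[i][bit]
            gray = gray_new
            term = mpmath.mpf(1)
            for v in row_sums:
                term *= v
            if (W - gray.bit_count()) & 1:
                term = -term
            total += term
        return total


def log_permanent(matrix, engine: str = "auto") -> float:
    """Log of the permanent of a non-negative matrix.

    ``matrix`` is a :class:`LikelihoodMatrix`, a log-entry array, or a
    plain non-negative array (converted to logs). Engines: ``"naive"``
    (log-sum-exp over all W! permutations, exact, default for small W),
    ``"ryser"`` (Gray-code inclusion-exclusion with per-row scaling,
    compensated summation and an arbitrary-precision retry on detected
    cancellation), or ``"auto"``.
    """
    if isinstance(matrix, LikelihoodMatrix):
        logA = matrix.log_entries
    else:
        logA = np.asarray(matrix, dtype=np.float64)
        if logA.ndim != 2 or logA.shape[0] != logA.shape[1]:
            raise DomainError("matrix must be square")
    W = logA.shape[0]
    if W > MAX_PERMANENT_W:
        raise PermanentSizeError(
            f"exact permanent computation is capped at W={MAX_PERMANENT_W} "
            f"(requested W={W}); the cost is O(W 2^W) and doubles per event. "
            "Use the ABC estimators for large event sets.")
    if engine == "auto":
        engine = "naive" if W <= _NAIVE_DEFAULT_MAX else "ryser"
    if engine == "naive":
        return _log_permanent_naive(logA)
    if engine == "ryser":
        return _log_permanent_ryser(logA)
    raise DomainError(f"unknown permanent engine {engine!r}")


def log_permanent_of_values(A: np.ndarray, engine: str = "auto") -> float:
    """Convenience wrapper: permanent of a matrix given in linear scale."""
    A = np.asarray(A, dtype=np.float64)
    if np.any(A < 0):
        raise DomainError("matrix entries must be non-negative")
    with np.errstate(divide="ignore"):
        return log_permanent(np.log(A), engine=engine)


# ---------------------------------------------------------------------------
# Likelihood terms


def _model_for(lambda_: float, W: SizeLike, q: int = 0) -> ZipfMandelbrotModel:
    if q == 0:
        return PowerLawModel(lambda_=lambda_, W=W)
    return ZipfMandelbrotModel(lambda_=lambda_, q=q, W=W)


def leading_term_loglik(counts, lambda_: float, W: SizeLike) -> float:
    """Log of the identity-permutation term: the likelihood the prevailing
    estimators maximize (valid only if empirical rank = probability rank).

    Equals ``sum_r n(r) * (-lambda ln r - ln Z)`` over observed ranks;
    events beyond W_obs contribute a factor of 1.
    """
    c = _as_counts_array(counts)
    if not is_unbounded(W) and W < c.size:
        raise DomainError(f"W={W} smaller than W_obs={c.size}")
    if c.size == 0:
        raise DomainError("empty counts")
    Z = normalizer(lambda_, W)
    ranks = np.arange(1, c.size + 1, dtype=np.float64)
    return float(np.sum(c * (-lambda_ * np.log(ranks))) - c.sum() * math.log(Z))


def permutation_term_loglik(counts, mapping: RankMapping,
                            model: ZipfMandelbrotModel) -> float:
    """Log of a single permutation's term: sum_r n(s(r)) * ln p(r).

    Counts are zero-padded to the mapping's length W; the mapping must be a
    permutation of 1..W.
    """
    if not isinstance(mapping, RankMapping):
        mapping = RankMapping(np.asarray(mapping))
    c = _as_counts_array(counts)
    W = mapping.W
    if W < c.size:
        raise DomainError(f"mapping length {W} smaller than W_obs={c.size}")
    padded = np.zeros(W, dtype=np.float64)
    padded[: c.size] = c
    log_p = np.asarray(model.log_pmf(np.arange(1, W + 1)), dtype=np.float64)
    return float(np.sum(padded[mapping.s - 1] * log_p))


def full_loglik(counts, lambda_: float, W: int, engine: str = "auto") -> float:
    """Log of the full permutation-sum likelihood, via the log-permanent
    of the likelihood matrix."""
    if is_unbounded(W):
        raise DomainError("the full permutation sum requires finite W "
                          "(it is the matrix permanent over W events)")
    model = _model_for(lambda_, W)
    return log_permanent(LikelihoodMatrix.build(counts, model, W), engine=engine)


def _gradient_parts(counts, lambda_: float, W: int,
                    engine: str = "auto") -> tuple[float, float, float]:
    """Shared machinery for the gradient and the score.

    Returns (log L, log|G|, sign(G)) where G = dL/dlambda. Uses the
    permanent identity

        sum_s (sum_r n(s(r)) ln r) prod_i a_{i,s(i)} = sum_r ln r * perm(A^(r))

    with A^(r) equal to A with row r multiplied elementwise by n_j, so the
    derivative costs W extra permanent evaluations instead of a fresh W!
    sum.
    """
    c = _as_counts_array(counts)
    model = _model_for(lambda_, W)
    base = LikelihoodMatrix.build(c, model, W)
    logL = log_permanent(base, engine=engine)

    N = float(c.sum())
    Z = model.normalizer
    Zp = model.normalizer_derivative
    padded = np.zeros(W, dtype=np.float64)
    padded[: c.size] = c
    with np.errstate(divide="ignore"):
        log_n = np.log(padded)

    # log of sum_r>=2 ln r * perm(A^(r)), each perm on the log scale
    log_terms = []
    for r in range(2, W + 1):
        logA_r = base.log_entries.copy()
        logA_r[r - 1, :] += log_n  # zero counts become -inf entries
        lp = log_permanent(logA_r, engine=engine)
        if np.isfinite(lp):
            log_terms.append(math.log(math.log(r)) + lp)
    log_S = logsumexp(log_terms) if log_terms else -math.inf

    # G = -(N Z'/Z) L - S ; Z' < 0 so the first piece is positive
    a = math.log(-N * Zp / Z) + logL if Zp < 0 else -math.inf
    if a == -math.inf and log_S == -math.inf:
        return logL, -math.inf, 0.0
    log_abs, sign = logsumexp([a, log_S], b=[1.0, -1.0], return_sign=True)
    return logL, float(log_abs), float(sign)


def full_loglik_gradient(counts, lambda_: float, W: int,
                         engine: str = "auto") -> float:
    """Derivative of the (non-log) full likelihood with respect to lambda.

    Computed by the permutation machinery: each permutation's term carries
    the factor -(N Z'/Z + sum_r n(s(r)) ln r). Note the linear-scale value
    underflows double precision for large N; use :func:`full_score` for the
    log-derivative, which is always representable.
    """
    logL, log_abs, sign = _gradient_parts(counts, lambda_, W, engine)
    return sign * math.exp(log_abs)


def full_score(counts, lambda_: float, W: int, engine: str = "auto") -> float:
    """d/dlambda of the *log* full likelihood (gradient / likelihood);
    numerically stable at any N."""
    logL, log_abs, sign = _gradient_parts(counts, lambda_, W, engine)
    return sign * math.exp(log_abs - logL)


# ---------------------------------------------------------------------------
# Maximum-likelihood estimators


def _maximize_scalar(neg_obj, lo: float, hi: float) -> float:
    res = minimize_scalar(neg_obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": _OPT_XATOL})
    return float(res.x)


def _boundary(x: float, lo: float, hi: float, tol: float = 1e-4) -> str | None:
    if x - lo < tol:
        return "lower"
    if hi - x < tol:
        return "upper"
    return None


def mle_leading_unbounded(counts, *, ranks=None,
                          lambda_max: float = LAMBDA_MAX_DEFAULT) -> float:
    """Exponent MLE from the leading-term likelihood with an unbounded
    event set — the estimator popularized by Clauset et al., applied here
    with ranks starting at 1.

    maximizes  -N ln zeta(lambda) - lambda * sum_r n(r) ln r  over
    lambda in (1, lambda_max].

    ``ranks`` substitutes a-priori-known probability ranks for the default
    empirical ranks 1..W_obs (same likelihood, correct ranks) — the
    rank-identified estimator that is actually consistent.
    """
    if ranks is None:
        c = _as_counts_array(counts)
        ranks = np.arange(1, c.size + 1, dtype=np.float64)
    else:
        # counts aligned to a-priori ranks need not be monotone
        c = np.asarray(counts.counts if isinstance(counts, RankFrequencyCounts)
                       else counts, dtype=np.int64)
        ranks = np.asarray(ranks, dtype=np.float64)
        if ranks.size != c.size:
            raise DomainError("ranks and counts must align")
    sum_n_log_r = float(np.sum(c * np.log(ranks)))
    if sum_n_log_r == 0.0:
        raise BoundaryError(
            "all observations sit at rank 1 (ln 1 = 0): the leading-term "
            "likelihood increases without bound in lambda")
    N = float(c.sum())

    def neg(lmbda: float) -> float:
        return N * math.log(normalizer(lmbda, UNBOUNDED)) + lmbda * sum_n_log_r

    lo = _LAMBDA_MIN_UNBOUNDED
    lam = _maximize_scalar(neg, lo, lambda_max)
    side = _boundary(lam, lo, lambda_max)
    if side == "upper":
        raise BoundaryError(f"maximizer hit lambda_max={lambda_max}")
    if side == "lower":
        # legitimate for heavy-tailed data with true lambda near 1; warn only
        warnings.warn("leading-term MLE at the lower search bound (lambda ~ 1)",
                      RuntimeWarning, stacklevel=2)
    return lam


def mle_leading_finite(counts, W: int, *,
                       lambda_max: float = LAMBDA_MAX_DEFAULT) -> float:
    """Exponent MLE from the leading-term likelihood with a finite, known
    event set (Hanel et al.'s adaptation); lambda may be <= 1 here, so the
    search domain is [0, lambda_max]."""
    c = _as_counts_array(counts)
    if c.size < 1 or W < c.size:
        raise DomainError("need W >= W_obs >= 1")
    if W == 1:
        raise BoundaryError("W=1 leaves the exponent unidentified (p=1 always)")

    def neg(lmbda: float) -> float:
        return -leading_term_loglik(c, lmbda, W)

    lam = _maximize_scalar(neg, 0.0, lambda_max)
    side = _boundary(lam, 0.0, lambda_max)
    if side is not None:
        warnings.warn(f"finite-W leading-term MLE at the {side} search bound",
                      RuntimeWarning, stacklevel=2)
        if side == "lower":
            return 0.0
    return lam


def mle_full(counts, W: int | None = None, *,
             lambda_max: float = LAMBDA_MAX_DEFAULT,
             engine: str = "auto", cross_check: bool = True) -> float:
    """Exponent MLE from the full permutation-sum likelihood.

    Maximizes the log-permanent over lambda in [0, lambda_max] by bounded
    scalar optimization and, by default, cross-checks against a root of
    the score function; the two routes must agree within 1e-4.

    ``W`` defaults to the number of observed events.
    """
    c = _as_counts_array(counts)
    if W is None:
        W = c.size
    if c.size < 1 or W < c.size:
        raise DomainError("need W >= W_obs >= 1")
    if W == 1:
        raise BoundaryError("W=1 leaves the exponent unidentified (p=1 always)")

    def neg(lmbda: float) -> float:
        return -full_loglik(c, lmbda, W, engine=engine)

    lam = _maximize_scalar(neg, 0.0, lambda_max)
    side = _boundary(lam, 0.0, lambda_max)
    if side is not None:
        warnings.warn(f"full-likelihood MLE at the {side} search bound",
                      RuntimeWarning, stacklevel=2)
        return 0.0 if side == "lower" else lam

    if cross_check:
        score = lambda l: full_score(c, l, W, engine=engine)
        lo, hi = max(lam - 0.5, 1e-6), min(lam + 0.5, lambda_max)
        s_lo, s_hi = score(lo), score(hi)
        if s_lo > 0 > s_hi:
            root = brentq(score, lo, hi, xtol=1e-8)
            if abs(root - lam) > 1e-4:
                raise InconsistencyError(
                    f"maximizer {lam:.6f} and score root {root:.6f} disagree")
    return lam
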