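"""Zipf and Zipf-Mandelbrot probability models over ranked discrete events.

The Zipf (discrete power-law / zeta) model assigns probability

    p(r_p) = r_p^(-lambda) / Z_lambda,      Z_lambda = sum_{r=1}^{W} r^(-lambda)

to the event of probability rank ``r_p``, where ``W`` is the size of the
event set. ``W`` may be the distinguished value :data:`UNBOUNDED`, in which
case the normalizer is the Riemann zeta function and the exponent must
exceed 1 for the distribution to exist. The Zipf-Mandelbrot generalization
flattens the head of the distribution with an integer offset ``q``:

    p(r_p) ∝ (r_p + q)^(-lambda),      q in {0, 1, 2, ...}

Both models come with exact samplers. A draw of ``N`` events yields both
the empirical rank-frequency data (counts sorted most- to least-frequent)
and the realized mapping from probability ranks to empirical ranks, so that
downstream estimators can be evaluated on either representation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Union

import mpmath
import numpy as np

from ._errors import DivergenceError, DomainError
from .rankfreq import RankFrequencyCounts, RankMapping

#: Distinguished event-set size for models over an unbounded (countable) set.
UNBOUNDED: float = math.inf

SizeLike = Union[int, float]

# Finite normalizer sums switch to compensated (fsum) accumulation above
# this many terms; below it plain float64 summation is already exact enough.
_FSUM_THRESHOLD = 100_000


def is_unbounded(W: SizeLike) -> bool:
    """True if ``W`` denotes the unbounded event set."""
    return W == UNBOUNDED or (isinstance(W, str) and W == "unbounded")


def _validate_W(W: SizeLike) -> SizeLike:
    if is_unbounded(W):
        return UNBOUNDED
    if not (isinstance(W, (int, np.integer)) and W >= 1):
        raise DomainError(f"W must be a positive integer or UNBOUNDED, got {W!r}")
    return int(W)


def _validate_q(q: int) -> int:
    if not (isinstance(q, (int, np.integer)) and q >= 0):
        raise DomainError(f"q must be a non-negative integer, got {q!r}")
    return int(q)


def normalizer(lambda_: float, W: SizeLike = UNBOUNDED, q: int = 0) -> float:
    """Normalizing constant Z = sum_{r=1..W} (r+q)^(-lambda).

    For ``W = UNBOUNDED`` this is the Hurwitz zeta function zeta(lambda, 1+q)
    (the Riemann zeta function when q = 0), evaluated with mpmath at high
    precision; it diverges unless lambda > 1. Finite sums are computed by
    direct summation, compensated for very large W.
    """
    W = _validate_W(W)
    q = _validate_q(q)
    if is_unbounded(W):
        if lambda_ <= 1.0:
            raise DivergenceError(
                f"normalizer diverges for unbounded W with lambda={lambda_} <= 1"
            )
        return float(mpmath.zeta(lambda_, q + 1))
    ranks = np.arange(1, W + 1, dtype=np.float64) + q
    terms = ranks ** (-float(lambda_))
    if W > _FSUM_THRESHOLD:
        return math.fsum(terms)
    return float(terms.sum())


def normalizer_derivative(lambda_: float, W: SizeLike = UNBOUNDED, q: int = 0) -> float:
    """dZ/dlambda = -sum (r+q)^(-lambda) ln(r+q); zeta'(lambda) when unbounded.

    Always negative for event sets with at least two events (and exactly 0
    for W = 1, q = 0, since ln 1 = 0).
    """
    W = _validate_W(W)
    q = _validate_q(q)
    if is_unbounded(W):
        if lambda_ <= 1.0:
            raise DivergenceError(
                f"normalizer diverges for unbounded W with lambda={lambda_} <= 1"
            )
        # first derivative of the Hurwitz zeta with respect to s
        return float(mpmath.zeta(lambda_, q + 1, 1))
    ranks = np.arange(1, W + 1, dtype=np.float64) + q
    terms = -(ranks ** (-float(lambda_))) * np.log(ranks)
    if W > _FSUM_THRESHOLD:
        return math.fsum(terms)
    return float(terms.sum())


@dataclass
class ZipfMandelbrotModel:
    """Zipf-Mandelbrot distribution p(r_p) = (r_p+q)^(-lambda) / Z.

    Parameters
    ----------
    lambda_:
        Power-law exponent. Must exceed 1 when ``W`` is unbounded.
    q:
        Non-negative integer head-flattening offset. ``q = 0`` recovers the
        plain Zipf model exactly.
    W:
        Event-set size; a positive integer or :data:`UNBOUNDED`.
    """

    lambda_: float
    q: int = 0
    W: SizeLike = UNBOUNDED
    family: str = field(default="zipf_mandelbrot", repr=False)

    def __post_init__(self) -> None:
        self.W = _validate_W(self.W)
        self.q = _validate_q(self.q)
        if self.lambda_ < 0:
            raise DomainError(f"lambda must be non-negative, got {self.lambda_}")
        if is_unbounded(self.W) and self.lambda_ <= 1.0:
            raise DivergenceError(
                f"unbounded event set requires lambda > 1, got {self.lambda_}"
            )

    @cached_property
    def normalizer(self) -> float:
        return normalizer(self.lambda_, self.W, self.q)

    @cached_property
    def normalizer_derivative(self) -> float:
        return normalizer_derivative(self.lambda_, self.W, self.q)

    def _check_rank(self, r_p) -> None:
        r = np.asarray(r_p)
        if np.any(r < 1) or (not is_unbounded(self.W) and np.any(r > self.W)):
            raise DomainError(f"rank out of range 1..{self.W}: {r_p!r}")

    def pmf(self, r_p) -> float | np.ndarray:
        """Probability of the event with probability rank ``r_p`` (1-based)."""
        self._check_rank(r_p)
        r = np.asarray(r_p, dtype=np.float64)
        out = (r + self.q) ** (-self.lambda_) / self.normalizer
        return float(out) if out.ndim == 0 else out

    def log_pmf(self, r_p) -> float | np.ndarray:
        self._check_rank(r_p)
        r = np.asarray(r_p, dtype=np.float64)
        out = -self.lambda_ * np.log(r + self.q) - math.log(self.normalizer)
        return float(out) if out.ndim == 0 else out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "lambda": self.lambda_,
            "q": self.q,
            "W": "unbounded" if is_unbounded(self.W) else int(self.W),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class PowerLawModel(ZipfMandelbrotModel):
    """Plain Zipf (discrete power-law) distribution p(r_p) = r_p^(-lambda)/Z.

    Identical to :class:`ZipfMandelbrotModel` with the offset pinned at
    q = 0; the normalizer is the Riemann zeta function zeta(lambda) for the
    unbounded event set.
    """

    family: str = field(default="zipf", repr=False)

    def __post_init__(self) -> None:
        if self.q != 0:
            raise DomainError("PowerLawModel has q = 0 by definition; "
                              "use ZipfMandelbrotModel for q > 0")
        super().__post_init__()


def model_from_dict(d: dict) -> ZipfMandelbrotModel:
    """Inverse of :meth:`ZipfMandelbrotModel.to_dict`."""
    W = UNBOUNDED if d.get("W", "unbounded") == "unbounded" else int(d["W"])
    family = d.get("family", "zipf")
    if family == "zipf":
        return PowerLawModel(lambda_=float(d["lambda"]), W=W)
    if family == "zipf_mandelbrot":
        return ZipfMandelbrotModel(lambda_=float(d["lambda"]), q=int(d.get("q", 0)), W=W)
    raise DomainError(f"unknown model family {family!r}")


def model_from_json(s: str) -> ZipfMandelbrotModel:
    return model_from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Sampling


@dataclass(frozen=True)
class SampleResult:
    """Outcome of drawing N i.i.d. events from a ranked model.

    Attributes
    ----------
    counts:
        The empirical rank-frequency data: observed event counts sorted from
        most to least frequent (ties broken by probability rank, which does
        not affect any likelihood here).
    mapping:
        The realized permutation s over the *observed* events, ordered by
        probability rank: ``s[i] = r_e`` is the empirical rank of the i-th
        most probable observed event, i.e.
        ``counts[s[i] - 1] == prob_rank_counts[i]``.
    prob_ranks:
        True probability ranks r_p of the observed events, ascending.
        Unobserved events (possible for any model when N is small relative
        to the tail) are omitted; they carry no likelihood information.
    prob_rank_counts:
        Counts aligned with ``prob_ranks`` — the "a priori known ranks"
        representation of the same sample.
    """

    counts: RankFrequencyCounts
    mapping: RankMapping
    prob_ranks: np.ndarray
    prob_rank_counts: np.ndarray


def _draw_prob_ranks(model: ZipfMandelbrotModel, N: int,
                     rng: np.random.Generator) -> np.ndarray:
    """N i.i.d. probability ranks from the model."""
    if not is_unbounded(model.W):
        # exact inverse-CDF lookup on the cumulative probability table
        probs = model.pmf(np.arange(1, model.W + 1))
        cdf = np.cumsum(probs)
        cdf[-1] = 1.0
        return np.searchsorted(cdf, rng.random(N), side="right") + 1
    # Unbounded: numpy's Generator.zipf is an exact rejection sampler for
    # the zeta distribution (Devroye's dominating-envelope scheme), valid
    # for lambda > 1.
    if model.q == 0:
        return rng.zipf(model.lambda_, N)
    # Zipf-Mandelbrot (q > 0): rejection against a shifted continuous
    # Pareto envelope. Draw X with density proportional to (x+q)^(-lambda)
    # on [0, inf) by inverse CDF, take r = floor(X) + 1 and accept with
    # probability ((X+q)/(r+q))^lambda <= 1. The envelope integral over
    # [r-1, r) dominates the target mass at r exactly, so the scheme is
    # exact; its acceptance rate stays near 1 for all (lambda, q).
    lam, q = model.lambda_, float(model.q)
    out = np.empty(N, dtype=np.int64)
    filled = 0
    # draws beyond int64 range are resampled (they would be singletons of
    # astronomically large rank; the same guard numpy's zipf applies)
    huge = float(2**62)
    while filled < N:
        batch = max(int(1.2 * (N - filled)), 1024)
        u = rng.random(batch)
        with np.errstate(over="ignore", invalid="ignore"):
            # overflow -> inf -> rejected by the range guard and resampled
            x = q * u ** (-1.0 / (lam - 1.0)) - q
            r = np.floor(x) + 1.0
            accept = (rng.random(batch) < ((x + q) / (r + q)) ** lam) & (r < huge)
        x = r[accept]
        take = min(len(x), N - filled)
        out[filled:filled + take] = x[:take].astype(np.int64)
        filled += take
    return out


def sample_counts(model: ZipfMandelbrotModel, N: int, seed) -> SampleResult:
    """Draw N events and return rank-frequency counts plus the rank mapping.

    ``seed`` may be an integer or a ``numpy.random.Generator``. Identical
    (model, N, integer seed) always reproduces identical output.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = _draw_prob_ranks(model, N, rng)

    if is_unbounded(model.W):
        prob_ranks, prob_rank_counts = np.unique(draws, return_counts=True)
    else:
        prob_rank_counts = np.bincount(draws, minlength=model.W + 1)[1:]
        prob_ranks = np.arange(1, model.W + 1, dtype=np.int64)

    # Empirical order: sort by count descending; stable sort keeps ties in
    # ascending probability-rank order.
    order = np.argsort(-prob_rank_counts, kind="stable")
    sorted_counts = prob_rank_counts[order]
    observed = sorted_counts > 0
    counts = RankFrequencyCounts(sorted_counts[observed])

    # mapping restricted to observed events, re-indexed by probability order
    emp_rank_of = np.empty(len(order), dtype=np.int64)
    emp_rank_of[order] = np.arange(1, len(order) + 1)
    obs_mask = prob_rank_counts > 0
    obs_emp = emp_rank_of[obs_mask]
    # compress empirical ranks of observed events to 1..W_obs (for a finite
    # W they already are: observed events sort ahead of zero counts)
    mapping = RankMapping(np.argsort(np.argsort(obs_emp)) + 1)

    return SampleResult(
        counts=counts,
        mapping=mapping,
        prob_ranks=prob_ranks[obs_mask],
        prob_rank_counts=prob_rank_counts[obs_mask],
    )
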