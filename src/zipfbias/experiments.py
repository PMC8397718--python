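"""Simulation studies: bias/variance sweeps, the small worked example, and
the book-analysis pipeline.

The sweeps quantify the headline phenomenon: applied to empirical
rank-frequency data, the leading-term (rank-identified) MLE overestimates
the exponent — strongly so for exponents near 1 — while the same
likelihood applied to a-priori-known probability ranks is consistent, and
the ABC estimators remove most of the bias. Each sweep cell is seeded
independently (``base_seed + setting_index * 10**6 + replicate``) so any
cell can be re-run in isolation; estimator failures are recorded per
replicate and excluded from aggregates, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import ZipfBiasError
from .abc_engine import ABCConfig, abc_pmc, abc_regression
from .exact_likelihood import (full_loglik, full_score, leading_term_loglik,
                               mle_full, mle_leading_finite,
                               mle_leading_unbounded)
from .models import PowerLawModel, SampleResult, sample_counts
from .rankfreq import RankFrequencyCounts, counts_from_tokens, read_tokens

__all__ = [
    "SweepResult",
    "ESTIMATORS",
    "bias_sweep_lambda",
    "bias_sweep_N",
    "worked_example",
    "analyze_book",
]


# ---------------------------------------------------------------------------
# Estimator registry: name -> callable(sample, seed, abc_config) -> lambda_hat


def _est_clauset(sample: SampleResult, seed: int, cfg: ABCConfig) -> float:
    """Leading-term unbounded MLE on the empirical rank-frequency data."""
    return mle_leading_unbounded(sample.counts)


def _est_clauset_known_ranks(sample: SampleResult, seed: int,
                             cfg: ABCConfig) -> float:
    """The same likelihood evaluated at the true probability ranks — the
    rank-identified estimator, consistent by construction."""
    return mle_leading_unbounded(sample.prob_rank_counts,
                                 ranks=sample.prob_ranks)


def _est_abc_pmc(sample: SampleResult, seed: int, cfg: ABCConfig) -> float:
    _, post = abc_pmc(sample.counts, "zipf", replace(cfg, seed=seed))
    return post.map_estimate


def _est_abc_regression(sample: SampleResult, seed: int,
                        cfg: ABCConfig) -> float:
    post = abc_regression(sample.counts, "zipf", replace(cfg, seed=seed))
    return post.point_estimate


ESTIMATORS: dict[str, Callable] = {
    "clauset": _est_clauset,
    "clauset_known_ranks": _est_clauset_known_ranks,
    "abc_pmc": _est_abc_pmc,
    "abc_regression": _est_abc_regression,
}


@dataclass(frozen=True)
class SweepResult:
    """Aggregated sweep output.

    ``table`` has one row per (setting, estimator) with columns: setting,
    estimator, mean_estimate, bias, bias_ci68_low, bias_ci68_high,
    variance, reps, failures. ``estimates`` keeps the raw per-replicate
    values for downstream analysis.
    """

    table: pd.DataFrame
    estimates: pd.DataFrame
    setting_axis: str
    base_seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _aggregate(rows: list[dict], raw: list[dict], axis: str,
               base_seed: int) -> SweepResult:
    return SweepResult(table=pd.DataFrame(rows), estimates=pd.DataFrame(raw),
                       setting_axis=axis, base_seed=base_seed)


def _run_cells(settings: Sequence, make_sample: Callable, true_lambda: Callable,
               reps: int, estimators: Iterable[str], base_seed: int,
               abc_config: ABCConfig | None, axis: str) -> SweepResult:
    names = list(estimators)
    unknown = set(names) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    cfg = abc_config or ABCConfig()
    rows, raw = [], []
    for j, setting in enumerate(settings):
        per_est: dict[str, list[float]] = {n: [] for n in names}
        failures: dict[str, int] = {n: 0 for n in names}
        for k in range(reps):
            seed = base_seed + j * 10**6 + k
            sample = make_sample(setting, seed)
            for name in names:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        est = ESTIMATORS[name](sample, seed, cfg)
                    per_est[name].append(est)
                    raw.append({"setting": setting, "estimator": name,
                                "replicate": k, "estimate": est})
                except ZipfBiasError:
                    failures[name] += 1
        lam = true_lambda(setting)
        for name in names:
            vals = np.asarray(per_est[name])
            n_ok = vals.size
            mean = float(vals.mean()) if n_ok else np.nan
            var = float(vals.var(ddof=1)) if n_ok > 1 else (0.0 if n_ok else np.nan)
            se = float(np.sqrt(var / n_ok)) if n_ok > 1 else np.nan
            bias = mean - lam
            rows.append({
                "setting": setting, "estimator": name, "mean_estimate": mean,
                "bias": bias,
                "bias_ci68_low": bias - se, "bias_ci68_high": bias + se,
                "variance": var, "reps": n_ok, "failures": failures[name],
            })
    return _aggregate(rows, raw, axis, base_seed)


def bias_sweep_lambda(lambdas: Sequence[float], N: int, reps: int,
                      estimators: Iterable[str] = ("clauset",),
                      seed: int = 0,
                      abc_config: ABCConfig | None = None) -> SweepResult:
    """Bias/variance of estimators across true exponents (unbounded Zipf).

    For each lambda, ``reps`` datasets of size N are sampled and every
    estimator is applied to the empirical rank-frequency data (or to the
    known-rank representation, for the rank-identified estimator).
    """
    if reps < 2:
        raise ValueError("need reps >= 2 for a variance estimate")
    if any(l <= 1 for l in lambdas):
        raise ValueError("unbounded sampling requires every lambda > 1")

    def make(lam: float, s: int) -> SampleResult:
        return sample_counts(PowerLawModel(lambda_=lam), N, s)

    return _run_cells(list(lambdas), make, lambda lam: lam, reps, estimators,
                      seed, abc_config, axis="lambda")


def bias_sweep_N(lambda_true: float, Ns: Sequence[int], reps: int,
                 estimators: Iterable[str] = ("clauset",),
                 seed: int = 0,
                 abc_config: ABCConfig | None = None) -> SweepResult:
    """Bias/variance of estimators across sample sizes at a fixed exponent."""
    if reps < 2:
        raise ValueError("need reps >= 2 for a variance estimate")

    def make(N: int, s: int) -> SampleResult:
        return sample_counts(PowerLawModel(lambda_=lambda_true), int(N), s)

    return _run_cells(list(Ns), make, lambda N: lambda_true, reps, estimators,
                      seed, abc_config, axis="N")


# ---------------------------------------------------------------------------
# Small worked example


WORKED_EXAMPLE_COUNTS = (10, 3, 3, 2, 1, 1)


def worked_example(counts: Sequence[int] = WORKED_EXAMPLE_COUNTS,
                   W: int | None = None,
                   lambda_grid: np.ndarray | None = None) -> dict:
    """Leading-term vs full-likelihood comparison on a small count vector.

    Computes both log-likelihood curves and both score (log-derivative)
    curves over a lambda grid, plus both MLEs. The default data
    [10, 3, 3, 2, 1, 1] with W = 6 is small enough that the full
    permutation sum (720 terms) is exact and fast, and the two estimators
    disagree visibly: the rank-identified leading term peaks at a larger
    exponent than the full permutation sum.
    """
    counts = list(counts)
    if W is None:
        W = len(counts)
    if lambda_grid is None:
        lambda_grid = np.linspace(0.5, 2.5, 101)
    rows = []
    for lam in lambda_grid:
        rows.append({
            "lambda": float(lam),
            "leading_loglik": leading_term_loglik(counts, float(lam), W),
            "full_loglik": full_loglik(counts, float(lam), W),
            "full_score": full_score(counts, float(lam), W),
        })
    curves = pd.DataFrame(rows)
    return {
        "counts": counts,
        "W": W,
        "mle_leading": mle_leading_finite(counts, W),
        "mle_full": mle_full(counts, W),
        "curves": curves,
    }


# ---------------------------------------------------------------------------
# Book pipeline


def analyze_book(text_path, methods: Iterable[str] = ("clauset", "abc_pmc",
                                                      "abc_regression"),
                 abc_config: ABCConfig | None = None,
                 seed: int = 0) -> dict:
    """Estimate the Zipf exponent of a text with several estimators.

    The text is cleaned (lowercase, punctuation stripped, digit runs
    replaced by '#'), tokenized on whitespace and reduced to
    rank-frequency counts; each requested estimator then runs on those
    counts. Per-method failures are reported, not raised. Divergence
    between the ABC variants on real text is the expected signature of
    model misspecification — natural language is not an i.i.d. draw from
    a Zipf distribution.
    """
    tokens = read_tokens(text_path)
    if not tokens:
        raise ValueError(f"no tokens found in {text_path}")
    counts = counts_from_tokens(tokens)
    return analyze_counts(counts, methods, abc_config, seed)


def analyze_counts(counts: RankFrequencyCounts,
                   methods: Iterable[str] = ("clauset", "abc_pmc",
                                             "abc_regression"),
                   abc_config: ABCConfig | None = None,
                   seed: int = 0) -> dict:
    """Per-method exponent estimates for pre-computed counts."""
    cfg = abc_config or ABCConfig()
    sample = SampleResult(counts=counts, mapping=None, prob_ranks=None,
                          prob_rank_counts=None)
    result: dict = {"N": counts.N, "W_obs": counts.W_obs, "estimates": {},
                    "errors": {}}
    for name in methods:
        if name not in ESTIMATORS:
            raise ValueError(f"unknown estimator {name!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                result["estimates"][name] = ESTIMATORS[name](sample, seed, cfg)
        except ZipfBiasError as exc:
            result["errors"][name] = f"{type(exc).__name__}: {exc}"
    return result
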