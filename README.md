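# zipfbias

Estimation of power-law (Zipf / Zipf–Mandelbrot) exponents from
rank-frequency data — with the rank-identification bias taken seriously.

## The problem

Rank each word of a book by how often it appears and the count of the
r-th word falls roughly as `n(r) ∝ r^(−γ)` with γ ≈ 1 — Zipf's law. The
probabilistic version models events as i.i.d. draws with
`p(r_p) = r_p^(−λ)/Z_λ`, where `r_p` is an event's rank in the *true*
probability distribution and `Z_λ = Σ r^(−λ)` (the Riemann zeta function
ζ(λ) for an unbounded event set). The standard discrete power-law MLE
maximizes

    log L_lead(λ) = Σ_r n(r) (−λ ln r − ln Z_λ),

which silently assumes the empirical rank of every event equals its
probability rank. For rank-frequency data that assumption is false — rank
and frequency are extracted from the same sample — and the estimator is
biased upward, strongly so for λ ≲ 1.5, exactly the range of natural
language and many rank-abundance data sets.

The correct likelihood marginalizes over every permutation `s` mapping
probability ranks to empirical ranks:

    L(λ | n) = Σ_{s ∈ S(W)} Π_{r_p=1}^{W} p(r_p)^{n(s(r_p))},

the permanent of the matrix `a[i][j] = p(i)^{n_j}` — exact, unbiased, and
#P-hard (Ryser's algorithm, O(W·2^W), is the best exact route). This
package provides:

* **`zipfbias.models`** — Zipf and Zipf–Mandelbrot (`p ∝ (r+q)^(−λ)`)
  models with exact normalizers, derivatives and exact samplers (finite
  and unbounded event sets), returning both the rank-frequency data and
  the realized rank permutation;
* **`zipfbias.exact_likelihood`** — the full permutation-sum likelihood
  via log-domain permanents (naive and Ryser engines, W ≤ 25), its
  derivative and score, and three MLEs: leading-term unbounded
  (Clauset-style), leading-term finite-W (Hanel-style), and the full
  permutation-sum estimator;
* **`zipfbias.abc_engine`** — likelihood-free estimators for real-scale
  data: ABC rejection, ABC population Monte Carlo with the 1-D
  Wasserstein distance between count vectors, and Beaumont-style ABC
  regression on the mean-log-count summary; weighted-KDE posteriors with
  MAP and credible intervals, for 1-parameter Zipf and 2-parameter
  Zipf–Mandelbrot models;
* **`zipfbias.rankfreq`** — rank-frequency containers, text cleaning and
  tokenization, distances, plain-text I/O;
* **`zipfbias.experiments`** — bias/variance sweeps across exponents and
  sample sizes, the small worked example, and the book-analysis pipeline;
* a `zipfbias` CLI wrapping all of the above.

## Worked example

The count vector `n = [10, 3, 3, 2, 1, 1]` (W = 6 events, N = 20
observations) is small enough for the exact 720-term likelihood:

```
$ zipfbias worked-example
{
  "counts": [10, 3, 3, 2, 1, 1],
  "W": 6,
  "mle_leading": 1.2664616061599434,
  "mle_full": 1.1580860173823524,
  ...
}
```

The leading-term (rank-identified) likelihood peaks at λ̂ = 1.27 while
the full permutation-sum likelihood peaks at λ̂ = 1.16: counting the ways
tail events can swap ranks shifts the optimum down. The same comparison
is available in Python via `zipfbias.worked_example()`, which also
returns both likelihood and score curves on a λ grid.

For data at real scale, the ABC route (here on a sample of N = 10,000
drawn at λ = 1.5):

```python
>>> from zipfbias import PowerLawModel, sample_counts, ABCConfig, abc_pmc
>>> obs = sample_counts(PowerLawModel(1.5), 10_000, seed=42).counts
>>> pop, post = abc_pmc(obs, "zipf", ABCConfig(seed=1))
>>> post.map_estimate
1.4979999999999998
>>> post.credible_interval(0.95)
(1.4832032416716878, 1.5122638509012232)
```

At λ = 1.1 the contrast is stark: across 10 such datasets (N = 10,000)
the leading-term MLE averages 1.176 — a bias of +0.076, growing as
λ → 1 — while the ABC-PMC MAP averages 1.0995.

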