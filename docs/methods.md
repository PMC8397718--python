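# Methods

## The estimation problem

Rank-frequency data are counts of discrete, unordered events — word
occurrences in a text, species abundances in a survey — sorted from most
to least frequent. The standard model is the Zipf (discrete power-law)
distribution over probability ranks,

    p(r_p) = r_p^(-λ) / Z_λ,     Z_λ = Σ_{r=1}^{W} r^(-λ),

with `W` the number of possible events (possibly unbounded, in which case
`Z_λ = ζ(λ)` and λ > 1 is required), and its Zipf–Mandelbrot
generalization `p(r_p) ∝ (r_p + q)^(-λ)` with integer offset `q ≥ 0`
flattening the head.

The subtlety is that an event's *empirical* rank `r_e` (its position in
the observed frequency ordering) is not its *probability* rank `r_p`. The
two are linked by an unknown permutation `s` with `s(r_p) = r_e`. The
widely used discrete power-law MLE treats `r_e` as if it were `r_p` —
i.e., it maximizes only the identity-permutation term

    log L_lead(λ) = Σ_r n(r) (−λ ln r − ln Z_λ),

which is a correct likelihood only when ranks are known a priori. The
correct likelihood for rank-frequency data marginalizes over all
assignments of probability ranks to empirical ranks:

    L(λ | n) = Σ_{s ∈ S(W)} Π_{r_p=1}^{W} p(r_p)^{n(s(r_p))}.

Unobserved events (when `W > W_obs`) enter with exponent 0, so the sum is
well defined as `W → ∞`. Because low-probability tail events are
undersampled, empirical ranks "bunch up" above the true distribution and
the leading-term MLE overestimates λ, most strongly for λ near 1 — the
range typical of natural language. The full sum removes that bias but is
a matrix permanent, hence #P-hard; this package computes it exactly for
small `W` and falls back on likelihood-free inference for real data.

## Exact computation (small W)

`L(λ|n)` equals the permanent of the W×W matrix `a[i][j] = p(i)^{n_j}`
(row = probability rank, column = empirical rank; the permanent is
transpose-invariant). Entries underflow double precision for realistic
counts, so everything is carried in log space:

* **naive engine** (default W ≤ 8): log-sum-exp over all W! permutation
  terms; exact, and the cross-check oracle for the other engine.
* **Ryser engine** (9 ≤ W ≤ 25): Gray-code inclusion–exclusion,
  O(W·2^W). Each row is scaled by its largest log-entry so linear-scale
  values lie in (0, 1]; the alternating sum is accumulated with Kahan
  compensation, and if the result retains fewer than ~6 significant
  digits (ratio of result to largest partial term below 1e-6) the sum is
  recomputed in mpmath arbitrary precision. A hard cap at W = 25 keeps
  the cost honest — the point of the exact route is precisely that it
  does not scale.

The likelihood derivative uses a permanent identity rather than a second
enumeration: with `A^(r)` denoting `A` with row `r` multiplied
elementwise by the counts, `dL/dλ = −(N Z'_λ/Z_λ) perm(A) − Σ_{r≥2}
ln r · perm(A^(r))`, i.e. W extra permanent evaluations. The score
(d/dλ log L) is formed from log-permanents only, so it is representable
at any N. Maximization uses bounded Brent (`xatol = 1e-6`) on
λ ∈ [0, 4] (finite W) or (1 + 1e-9, 4] (unbounded); the maximizer is
cross-checked against a Brent root of the score and the two must agree
within 1e-4. Search-bound hits raise or warn; they are never silently
clamped.

## Samplers

* Finite W: inverse-CDF lookup on the cumulative probability table
  (exact, O(log W) per draw).
* Unbounded Zipf: numpy's `Generator.zipf`, an exact Devroye-style
  rejection sampler for the zeta distribution (λ > 1). No truncation is
  introduced: for λ near 1 any feasible truncation would carry
  non-negligible tail mass and bias exactly the experiments this package
  runs.
* Unbounded Zipf–Mandelbrot (q > 0): exact rejection against a shifted
  continuous Pareto envelope — draw X with density ∝ (x+q)^(−λ) on
  [0, ∞) by inverse CDF, set r = ⌊X⌋ + 1, accept with probability
  ((X+q)/(r+q))^λ. The envelope integral over [r−1, r) dominates the
  target mass at r exactly, and the acceptance rate stays near 1 across
  the whole prior range (a naive thinning of zeta draws degrades to
  ~1e-3 acceptance at large q and λ). Draws beyond 2^62 are resampled,
  matching numpy's own guard; only astronomically-ranked singletons are
  affected.

Every sampling operation takes a single integer seed, mapped to numpy's
PCG64 generator, so seeded outputs are stable across sessions.
ζ(λ), the Hurwitz ζ(λ, q+1) and their λ-derivatives are evaluated with
mpmath; finite normalizer sums are direct, switching to compensated
summation above 10^5 terms.

## ABC estimators

All three likelihood-free routes simulate datasets with N equal to the
observed N (the distance then compares like with like) under uniform
priors: λ ~ U(1.001, 3.0) for unbounded models (U(0.5, 3.0) is a
sensible finite-W choice), q ~ U{0..20}.

**Distance.** The 1-Wasserstein distance between count vectors: sort
both non-increasing, zero-pad the shorter to the common length L, and
take the mean absolute rank-wise difference (the optimal quantile
coupling in one dimension). Zero-padding makes the distance sensitive to
vocabulary-size differences — precisely the tail behaviour that carries
the information the leading-term likelihood mishandles. An unpadded and
a log1p-count variant exist for sensitivity analysis. One caveat
documented here because a test found it: normalizing by the
pair-dependent L means the triangle inequality holds within a common
padded length but can fail across mixed-length triples; ABC only ever
compares simulations against one fixed observation, so no algorithm here
depends on that property.

**Rejection.** Accept prior draws whose distance falls below a fixed ε
until `n_particles` are collected (uniform weights); a simulation cap
(default 100 × n_particles) turns a hopeless tolerance into an error
rather than a hang.

**Population Monte Carlo.** Generation 0 accepts the first
`n_particles` prior draws. Generation t ≥ 1: resample a particle by
weight, perturb with a Gaussian kernel whose variance (covariance, in
the 2-parameter case) is twice the weighted empirical (co)variance of
the previous generation — the standard PMC choice; discard proposals
outside the prior before simulating; accept at tolerance ε_t, the
survival-fraction quantile (default 0.5) of the previous generation's
accepted distances, which makes the schedule non-increasing by
construction. Weights follow the PMC importance correction
`w_i ∝ prior(θ_i) / Σ_j w_j K(θ_i | θ_j)`. The offset q is proposed from
the joint Gaussian kernel and rounded to the nearest integer; its kernel
density is evaluated on the continuous relaxation, a standard discrete-
parameter compromise. Defaults — 200 particles, 10 generations — were
chosen once as the smallest configuration that resolves a 0.01-wide
posterior mode at N = 10^4 in minutes on one core.

**Regression adjustment.** 10,000 prior draws are simulated and reduced
to the scalar summary S(n) = mean over observed events of ln(count); the
closest 10% by |S_sim − S_obs| are kept, an Epanechnikov-weighted
local-linear regression of λ on S is fitted, and each retained draw is
shifted along the fitted slope to the observed summary
(λ*_i = λ_i − β̂ (S_i − S_obs), clipped to the prior support). The
weighted mean of the adjusted sample is the point estimate.

**Posteriors.** Weighted Gaussian KDE (weighted Silverman bandwidth) on
a λ grid with step 0.001 spanning the prior, renormalized on the grid
(trapezoid) so it integrates to 1; q is a discrete axis — mass per
integer, no smoothing across q; the joint density stacks a per-q
conditional KDE scaled by that q's weight mass. The MAP is the grid
argmax; under the uniform priors it is proportional to a maximum
likelihood estimate. Central credible intervals come from the gridded
CDF. A degenerate population (all particles identical) yields a narrow
spike rather than a crash, and a zero-variance regression design raises
a DegenerateError.

## Text pipeline

Cleaning is deterministic and locale-independent: Unicode casefold;
characters in categories P* and S* removed (`#` exempt — it is the
number placeholder and must survive a second pass, making cleaning
idempotent); maximal digit runs (category Nd) replaced by a single `#`
(thousands separators are stripped first, so "1,000" → "#");
whitespace split. Ties between equal counts keep first-occurrence order,
which no likelihood here depends on. Other tokenization conventions
(hyphen or apostrophe splitting) can move book-level estimates at the
second decimal; the cleaning rules are fixed so results are at least
internally comparable.

## Simulation experiments

`bias_sweep_lambda` / `bias_sweep_N` draw `reps` datasets per setting,
apply each registered estimator to the empirical rank-frequency data (or
the known-rank representation for the rank-identified control), and
report mean estimate, bias, a 68% normal-theory band on the bias,
variance, and a failure count — estimator boundary failures are logged
and excluded, never imputed. Replicate k of setting j uses seed
`base_seed + j·10^6 + k`, so any cell is independently re-runnable.
Desk-scale defaults (a handful of λ values, 10–20 replicates, N = 10^4)
reproduce the qualitative structure of the full sweeps (100 settings ×
100 replicates, N up to 10^6), which remain available by passing larger
grids.

What the generator does and does not emulate: synthetic data are exact
i.i.d. draws from the stated models, so recovery results certify the
estimators *under the model*. Real language is not an i.i.d. Zipf
process — word choice is bursty, topical and grammatical — and on real
text the two ABC variants legitimately disagree (each distance
prejudices different data features when no parameter value is "true").
Passing tests therefore demonstrate correct inference for
rank-abundance-type data generated by ranked-probability sampling, not
that any single exponent "is" the Zipf exponent of a book.

## Known limitations

* Exact full-likelihood inference is capped at W = 25 events by design;
  beyond that only the ABC routes apply.
* The unbounded leading-term MLE requires λ > 1; data whose maximizer
  sits at the boundary (e.g. a single observed event) raise BoundaryError.
* ABC tolerances are data-scale dependent (raw-count Wasserstein); the
  PMC quantile schedule absorbs this, but a fixed-ε rejection run needs
  a pilot to set ε sensibly.
* The regression-adjustment route is implemented for the 1-parameter
  family only.
* Very heavy tails (λ − 1 ≲ 10⁻³) put most zeta mass beyond 2^62; such
  draws are resampled, which perturbs only singleton events but makes
  estimates there effectively conditional on representable ranks.
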