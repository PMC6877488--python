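# Methods

## The evidence-updating replication Bayes factor

For data d and nested hypotheses H0 (point null) and H1 (a prior on the test
parameter), the Bayes factor BF10(d) = p(d | H1) / p(d | H0) is the ratio of
prior-predictive (marginal) likelihoods.  Posterior model odds are the prior
odds times the Bayes factor (`posterior_model_odds`).

Bayes factors are coherent under data splitting: if a prior is updated on
d_orig, the Bayes factor for d_rep under the updated prior satisfies

    BF10(d_orig, d_rep) = BF10(d_orig) · BF10(d_rep | d_orig).

The replication Bayes factor — evidence in the replication data when the
alternative's prior is the original study's posterior — is therefore the
complete-data Bayes factor divided by the original-study Bayes factor
(`replication_bf`).  This is how the package always computes it; no
posterior is ever approximated or re-expressed as a parametric prior.

`chain_evidence` generalizes to k ≥ 1 studies.  For the binomial design the
sequential terms come from explicit conjugate updating; for the t and
contingency designs they are defined as ratios of consecutive pooled-data
Bayes factors, which is the same quantity by the identity above.  With more
than two studies the procedure is a fixed-effects evidence synthesis: it
assumes the observations are exchangeable across studies.  All Bayes factors
are computed and stored in log space (`BayesFactorResult.log_bf10`);
reported values are conventionally rounded to 3 decimals, and ratios of
rounded values can disagree with direct computation in the third decimal
(e.g. a directly computed replication BF of 0.1036 where the ratio of
3-decimal components prints 0.103).

When a Bayes factor is below 1 the package reports both directions
(`bf10` and `bf01`) and flags the favored hypothesis rather than silently
switching direction in prose.

## Binomial design

Data: k successes in n trials.  H0: θ = θ₀ (default 0.5); H1: θ ~
Beta(α, β) (default the uniform Beta(1, 1)), optionally truncated to
[lower, upper] with the density renormalized.

Two computation paths are implemented and cross-checked on every call:

- **Savage–Dickey** (primary): BF01 = posterior density at θ₀ / prior
  density at θ₀, both renormalized under truncation; requires θ₀ strictly
  inside the prior support.
- **Marginal ratio**: p(d | H1) = C(n, k) · B(α + k, β + n − k)/B(α, β)
  times the ratio of truncation masses; p(d | H0) is the binomial pmf.
  These populate `marginal_h1` / `marginal_h0`, and the gap between the two
  paths is stored as `numerical_error` (it is at floating-point level).

All beta-function and density arithmetic uses log-gamma, so counts up to
10⁴ and far beyond are safe.  One-sided (order-restricted) variants truncate
the prior at θ₀ on the requested side; this equals the two-sided BF times
the posterior-to-prior mass ratio on that side.  Credible intervals are
central (equal-tailed), computed from (truncated) beta quantiles — central,
not HPD, is what matches the conventional reporting for this design.  The
classical parity statistic is the exact two-sided binomial test in the
minimum-likelihood convention (`scipy.stats.binomtest`), which reduces to
doubling the smaller tail at θ₀ = 0.5.

## Independent-samples t design

Data: either (t, n1, n2) or per-group (n, mean, sd) summaries, which are
sufficient for the pooled-variance t test.  With df = n1 + n2 − 2 and
effective sample size n_eff = n1·n2/(n1 + n2),

    BF10 = ∫ f_nct(t; df, δ√n_eff) π(δ) dδ / f_t(t; df),

where π(δ) is the effect-size prior: Cauchy (default, location 0, scale
√2/2 — the common default of Bayesian t-test software), normal, or
Student-t, optionally truncated to a half-line and renormalized.  The scale
default matters: it is the single tunable that moves these Bayes factors
materially; halving it roughly doubles BF10 for moderate t.

**Quadrature.**  δ is mapped to a bounded interval by
δ = location + scale·tan(u); the Jacobian cancels the Cauchy tails exactly
and compresses normal/Student-t tails harmlessly.  `scipy.integrate.quad`
runs at relative tolerance 1e−10 (absolute 1e−15, limit 200); the quad error
estimate, scaled by the H0 density, is reported as `numerical_error`.
Against an independent 400-node Gauss–Legendre evaluation the result is
stable to better than six significant digits, and a 10⁶-draw Monte-Carlo
prior-predictive estimate agrees within three Monte-Carlo standard errors.

**Pooling.**  Two studies' group summaries combine exactly, per group:
N = n_o + n_r, M = (n_o m_o + n_r m_r)/N, and

    SS = (n_o − 1)s_o² + (n_r − 1)s_r² + (n_o n_r / N)(m_o − m_r)²,

so the pooled summary equals the summary of the concatenated raw samples
(verified in tests against reconstructed raw vectors to 12 significant
digits).  Group 1 of each study must be the same experimental condition;
the study-record layer keeps the two groups in declared order, so files are
the place to get this right.  When only t statistics are available the
pooled t is *not* derivable — means and sds are the sufficient statistics —
so a replication report over t-statistic payloads requires an explicit
`role: combined` record carrying the published pooled t.

Out of scope by design: paired/one-sample variants, Welch-type unequal
variances, and raw-data ingestion (raw vectors appear only as test oracles).

## 2×2 contingency design

Data: a 2×2 table with row totals fixed (independent multinomial sampling;
each row is one experimental condition).  Under H1 each row's column
probabilities get an independent symmetric Dirichlet(a) prior; under H0 both
rows share a single column-probability vector with a symmetric Dirichlet(a)
prior.  Both marginal likelihoods are Dirichlet-multinomial closed forms in
log-gamma arithmetic, so the Bayes factor is exact.  The default
concentration a = 1 and the rows-fixed scheme are the defaults of the
point-and-click software whose outputs this test family is calibrated
against; a variant that instead gives the shared H0 vector the row-summed
concentration (2a per column) was considered and rejected because it does
not reproduce those reference outputs.  Other sampling schemes (Poisson,
joint multinomial, hypergeometric) and R×C tables raise
`NotImplementedError` loudly rather than falling back.

Pearson's χ² (no continuity correction, df = 1) is reported for parity.
Note the classical statistic for the worked original table is 4.519;
two-decimal citations of it elsewhere appear truncated rather than rounded.

## Order restriction and the replication paradox

A two-sided replication BF can paradoxically reward a replication whose
effect points the *opposite* way from the original (the pooled data may
still be far from the null).  The resolution is an order restriction: take
the effect direction observed in the original study, truncate the
alternative's prior to that side, and form the replication BF from
one-sided complete and original BFs.  The report layer implements this as
`direction_policy="order_restricted_by_original"` for the binomial and t
designs (the independence test has no signed effect in this parameterization,
so requesting it there is an error).  For an opposite-direction replication
the order-restricted replication BF is strictly smaller than the two-sided
one; for symmetric zero-centered priors the two one-sided BFs average to
the two-sided BF (both properties are asserted in the test suite).

## Synthetic study-series generators

`generate_binomial_series(theta_true, n_per_study, k_studies, seed)` draws
independent binomial studies at a common true rate; it emulates a sequence
of direct replications under perfect exchangeability.
`generate_ttest_series(delta_true, n_per_group, k_studies, seed, shift_sd)`
draws unit-variance normal groups separated by the standardized effect
`delta_true`; `shift_sd` adds a per-study location shift common to both
groups, emulating a nuisance-parameter change between labs (e.g. all
responses slower in the replication).  Defaults in the test suite use
desk-scale sizes (tens of trials per study, a handful of studies) so the
whole suite runs in seconds.

What these generators do **not** emulate: publication bias, questionable
flexibility in the original study, unequal variances, non-normal responses,
or heterogeneous true effects (random-effects structure).  Passing tests on
these series therefore demonstrate the internal coherence of the evidence
chain and the correctness of the computations — not robustness of the
method to non-exchangeable real data, which is a documented limitation:
pooling assumes the replication is direct and close, and large
nuisance-parameter shifts demonstrably erode pooled evidence for a real
effect (shown qualitatively in tests and `examples/synthetic_series.py`).

All generators require an explicit seed; there is no silent global RNG, and
two runs with the same seed produce byte-identical study records and
reports.

## Numerical and design choices

- Log-space everywhere; `BayesFactorResult` validates bf10↔log consistency
  and marginal-ratio consistency at construction.
- Reported rounding default: 3 decimals; JSON reports keep full precision
  and the text rendering rounds, so the two agree at the configured
  rounding.
- Binomial two-sided p convention: minimum-likelihood (doubling the tail at
  θ₀ = 0.5), chosen because it is the common exact-test convention; printed
  two-decimal p values in the literature for the worked examples appear
  truncated, so parity checks allow ±0.005.
- Degenerate inputs fail loudly: empty study lists, mixed designs,
  non-poolable summaries, zero margins, θ₀ outside the prior support, zero
  prior mass on a requested side, and nonpositive or non-finite Bayes
  factors all raise with the offending argument named.
- The t-test group split for a published t(26) with 28 participants is taken
  as 14/14 — the only split consistent with common equal-allocation
  reporting; the record format stores group sizes explicitly so unequal
  splits are fully supported when known.

## Known limitations

- Exchangeability is assumed by all pooling; mean-centering or other
  nuisance-absorbing transformations are not implemented.
- Correlation designs, random-effects synthesis, and effect-size
  equivalence testing across studies are out of scope.
- The contingency test covers only 2×2 tables with row totals fixed.
- The parameter-updating approximation to the t-test replication BF is not
  implemented, deliberately: the evidence-updating ratio is exact and needs
  no posterior approximation.
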