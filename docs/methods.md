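# Methods

This note records the model, the numerical choices and the design
decisions behind `elicitbn`, and what the synthetic experiments do and do
not demonstrate.

## Elicitation model

A judgment is a five-point summary (plausible lower limit, Q1, median,
Q3, plausible upper limit) of one expert's belief about one quantity.
Judgments are standardized by attaching probabilities
(t, 0.25, 0.5, 0.75, 1−t) to the five values; the tail probability t
defaults to **0.01** because plausible limits are elicited as bounds the
expert considers the true value highly unlikely to escape. t is
configurable, and a quartiles-only mode (`include_limits=False`) excludes
the limits from fitting so they constrain only the support. Both choices
are open in quartile-method practice; fitting the limits as (t, 1−t)
points is the default because it uses all five elicited numbers and keeps
the SSE comparable across candidate families (all families are scored on
the identical point set).

A judgment is *incomplete* when any of the five values is missing or all
five are identical (a degenerate "null" response). Incomplete judgments
are excluded per node (complete-case analysis); the retained count n is
the per-node expert denominator, which matters because the pooled
continuous prior carries **df = n − 1**.

## Distribution families

Eight candidates: normal; location-scale Student-T; shifted gamma
(L + Gamma); mirror gamma (U − Gamma); lognormal and log-T (log(X − L)
normal / Student-T); mirror log-T (log(U − X) Student-T); shifted-scaled
beta on [L, U]. Mirror constructions produce left-skewed shapes on
bounded support via Q_X(p) = U − Q_base(1 − p).

Decisions:

- **Shift/reflection anchors.** Log and shifted families anchor at the
  node's support lower bound when finite (zero for clinical
  non-negatives); mirror families need a finite upper anchor. When the
  node support is unbounded above, the elicited upper plausible limit
  stands in as the reflection bound by default
  (`bound_policy="elicited"`) — this is how left-skewed mirror fits arise
  for quantities like age and tumor size whose catalog support is
  [0, ∞). `bound_policy="support"` restricts anchors to catalog bounds,
  making mirror families inadmissible on unbounded nodes.
- **Per-expert T df.** With only 3–5 points, degrees of freedom are not
  estimable; T-type per-expert fits fix df = 3 (a conventional heavy-tail
  elicitation default), configurable. The pooled prior's df is governed by
  the n − 1 rule instead, and the pooled-quantile refit uses df = n − 1.
- **Moments of log-T-type families.** E[exp(T)] diverges for a Student-T
  of any df, so log-T and mirror log-T have no finite moments. Moment
  requests for them (and for plain T with df ≤ 2) raise an
  undefined-moment error unless the caller enables the truncated
  fallback: conditional moments on the central 0.001–0.999 quantile
  range, computed by adaptive quadrature (relative tolerance 1e−10) and
  flagged `"truncated"`. The pooling stage enables the fallback so that
  admissible heavy-tailed fits never crash the pipeline; truncation
  propagates into the flag on the pooled moments.
- Parameters are serialized by name ((loc, scale, df) for T-types,
  (shape, rate) for gammas, (α, β) for betas) to avoid convention drift.

## Least-squares quantile fitting

Objective: SSE(θ) = Σ_j (q_j − Q(p_j; θ))². Positive parameters are
log-transformed so the search space is unconstrained. The optimizer is
trust-region least squares (`scipy.optimize.least_squares`, tolerances
1e−13) from a moment-matched starting point (median/IQR estimates mapped
into each family's base space) plus five seeded jittered restarts
(N(0, 0.25²) in the unconstrained coordinates), with a short Nelder–Mead
polish when the residual landscape leaves the gradient step short of
numerical zero. Restarts stop early once SSE reaches numerical zero
relative to the data scale. Per-family quantile evaluation is specialized
to the fixed probability grid, so location-scale and log families cost
pure arithmetic per iteration.

Best-family selection compares SSE across all admissible families on the
same point set; SSE ties (within 1e−8 relative) go to the earlier family
in the fixed precedence order normal, T, shifted gamma, mirror gamma,
lognormal, log-T, mirror log-T, shifted-scaled beta. A tie rule is needed
because a single "best fitting" family is reported per expert; listing
order is the only non-arbitrary choice available.

## Pooling and priors

The linear opinion pool is the mixture f = Σ w_i f_i with equal weights
hard-defaulted; unequal weights require an explicit argument. Pooled
moments are closed-form mixture moments; the pooled quantile function
inverts the mixture CDF by Brent's method on a bracket built from the
union of component extreme quantiles (the bracket provably contains the
root for any mixture). Concordance is the census of per-expert best-fit
families, ties again by precedence.

Beta priors for proportion nodes come from moment matching
(α = mc, β = (1−m)c with c = m(1−m)/s² − 1), which requires
s² < m(1−m); infeasible pooled moments raise a named feasibility error
and the reporting layer converts it into a WARN flag — published tables
occasionally print moment pairs that violate the bound, and the package
flags rather than repairs them. The quantile-interpolation alternative
(`beta_quantile`) least-squares fits a beta quantile function to the
pooled quantiles at {0.01, 0.25, 0.5, 0.75, 0.99} (grid configurable) and
is preferred when the pooled shape is multimodal. Moment matching is the
default for proportion nodes; it is the stated construction for
categorical quantities, with interpolation as the fallback.

Continuous nodes default to the pooled-moment Student-T
(location = pooled mean, scale = pooled SD, df = n − 1);
`refit_best_family` instead re-runs best-family selection on the pooled
quantile grid, which can yield e.g. a mirror log-T prior when the pool is
left-skewed.

## Hybrid network

Nodes are continuous or categorical; roots carry priors, children carry
conditional models (CPT/tabulated over categorical parent combinations,
Gaussian linear, binary logistic, softmax multinomial). Categorical
values are 0-based category indices internally (the first listed category
is the reference whose proportion the beta prior describes); sample
tables expose labels.

- **Inference backend** is self-contained sampling: ancestral sampling in
  topological order and likelihood weighting for evidence (evidence nodes
  clamped, draws weighted by the product of evidence likelihoods given
  sampled parents, effective sample size reported). For a 12-node
  desk-scale network this is sufficient and avoids an external
  Gibbs/JAGS engine; chain-convergence diagnostics are therefore not
  applicable and are out of scope.
- **Categorical roots** use prior-predictive semantics by default: each
  draw samples a proportion from the beta prior, then the category. A
  `fixed_proportion` mode plugs in the beta mean instead; marginal
  category frequencies agree between the modes, but prior-predictive
  draws carry the prior's dispersion. Likelihood weighting under
  prior-predictive semantics weights by the sampled proportion itself,
  which integrates correctly over the latent proportion.
- **Continuous root priors are truncated to the node support** by
  inverse-CDF sampling (a T prior on a non-negative marker contributes
  only its mass on [0, ∞), renormalized). Evidence densities use the same
  truncated form.
- **Degenerate evidence** (zero total weight) raises an error rather than
  returning an empty posterior.

The shipped `paper_replica.yaml` encodes the twelve pancreatic-cancer
variables available at diagnosis with their published pooled priors.
Published continuous prior strings carry the pooled mean/SD rather than
any family's native parameters, so the replica uses truncated Student-T
priors with those moments and the published df for all three continuous
nodes. The edge set is illustrative (two edges into the neoadjuvant node,
anchored near its published pooled proportion) and documented as such in
the file: the true structure is a clinical modelling decision the priors
do not determine.

## Synthetic panels

`simulate_panel` gives each expert the truth's (0.01, 0.25, 0.5, 0.75,
0.99) quantiles plus Gaussian noise with SD = `judgment_noise_sd` × the
truth's IQR, clipped to support and re-sorted; the noise scales with node
units, so proportions and serum markers degrade comparably. Truths whose
elicited quantiles escape the declared support are rejected at
simulation time (otherwise clipping would silently distort the noiseless
panel). Designated experts return incomplete judgments in the two
patterns real panels show (missing lower limit; all-null). All randomness
flows from the single config seed.

The `paper_like()` preset (9 experts, 12 nodes, noise 0.05, the
published incomplete-response pattern: two incomplete for age, one for
tumor size, one for CA 19-9) uses beta truths matching the published
pooled moments for eight proportions, the published shape parameters for
the one beta-infeasible row, a shifted gamma for CA 19-9 and mirror
log-T truths for age and tumor size. It is an approximate emulation for
end-to-end testing — the real panel's raw judgments are not public — so
recovery results on it show pipeline correctness under these study
conditions, not properties of the real panel. In particular, noise is
symmetric and independent across experts; real expert error is neither,
and no anchoring or overconfidence dynamics are modelled.

## Problem sizes and tolerances

Tests use panels of 4–9 experts and networks of up to 12 nodes; Monte
Carlo checks use 10^4–10^6 draws with fixed seeds and 3-standard-error
bands; likelihood weighting is validated against exact enumeration on
4-node binary networks at 10^5 draws. Exact-recovery assertions use
SSE < 1e−8 and 1% parameter error; the beta moment round-trip is exact to
1e−10; mixture-quantile inversion to 1e−8; reflection identities to
1e−6 on a probability grid.

## Known limitations

- Least squares on quantiles has no likelihood interpretation; experts
  reporting the same quartiles with different tail behaviour are
  indistinguishable beyond the standardized limit points.
- The moment-matched beta and pooled-moment T summarize the pool by two
  moments; multimodal pools lose structure (the quantile-interpolation
  route mitigates, semi-parametric priors are out of scope).
- Conditional models for child nodes must be user-supplied; the package
  deliberately does not invent a mapping from marginal elicitation to
  conditional tables.
- Mirror fits on unbounded nodes depend on the elicited upper limit used
  as the reflection anchor; two experts with different limits get
  different anchor points, which is faithful to the elicitation but means
  the mirror family label is not comparable across experts in fine
  detail.
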