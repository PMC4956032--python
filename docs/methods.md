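# Methods notes

This note records the statistical model, the numerical and design choices,
and what the synthetic-data generators do and do not emulate. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Regression model

The response is ln femur length (ln cm); the predictor is a fixed binary
covariate z ∈ {0,1} (metaplastic projections present/absent). Residuals
follow Brownian motion on the tree, giving

y ~ MVN(Xβ, σ² C(λ, δ, κ)),  X = [1, z],

with C[i,j] the shared root-to-MRCA path length. The binary character is
treated as a known covariate — no evolutionary model for z enters the
regression (it gets its own Mk treatment for ancestral states). β₂ is a
group mean difference corrected for relatedness, hence "phylogenetic
t-test". A clade-concentrated predictor contributes few effective
phylogenetic contrasts, so β₂'s posterior is intrinsically wide in that
design; this is a property of the data layout, not of the estimator.

## Pagel transforms

- **λ ∈ [0,1]** multiplies the off-diagonal covariance entries. Implemented
  on the covariance (not as internal-branch scaling) so it is well defined
  on non-ultrametric trees; the two coincide for ultrametric trees.
- **δ ∈ (0,3]** raises covariance entries (shared path lengths) to a power.
  Applied to the matrix entries rather than to rebuilt node heights —
  identical for ultrametric trees, defined for all trees. Entrywise
  monotone powers preserve the nested (min-structured) form of a tree
  covariance, so the result stays PSD; the suite property-checks this.
- **κ ∈ [0,3]** raises each branch length to a power, with 0^κ = 0 for all
  κ (zero-length branches encode resolved polytomies and must stay zero)
  and κ = 0 mapping every positive branch to 1.

Composition order is fixed and recorded in every output: κ on branches →
build C → δ on entries → λ off-diagonal. The original analysis never
combines all three, but λ+δ and λ+κ models need a defined order. Caps
(default 3 for δ, κ) follow BayesTraits-style ranges and are configurable.

The root carries no branch; a root edge in input trees is ignored with a
logged warning, since BM covariance is defined from the root. Pruning
defaults to keeping the original root position (`keep_stem=True`), which
preserves the covariance submatrix of the retained taxa exactly; with
`keep_stem=False` the MRCA of the kept taxa becomes the root (pairwise tip
distances are preserved either way).

## Priors and MCMC

Priors (the source analysis is silent; these mirror flat/BayesTraits-style
defaults and are configurable): β₁, β₂ ~ N(0, 10²) on the ln-cm scale;
ln σ² uniform on [−20, 20]; λ ~ U(0,1); δ ~ U(0,3]; κ ~ U(0,3].

The sampler is Metropolis-within-Gibbs, one block per iteration chosen
uniformly at random:

- **β** — conjugate Gaussian full conditional, drawn exactly (Gibbs).
- **σ²** — inverse-gamma full conditional under the flat ln σ² prior
  (Inv-Gamma(n/2, q/2) with q the GLS quadratic form), drawn exactly.
- **each free transform** — Gaussian random walk, proposal scale adapted
  toward ~35% acceptance in 100-iteration windows during burn-in and frozen
  afterwards, so the retained chain has a fixed kernel.

Exact conditional draws for β and σ² remove nearly all autocorrelation in
the regression parameters, which matters at desk-scale chain lengths where
posterior-quantile noise otherwise dominates interval endpoints. All
likelihood evaluations go through Cholesky factorization (never explicit
inversion); a quadratic-form cache makes β/σ² updates O(1) given the
current factor. Proposals that leave a transform's range or make C
numerically singular are rejected. A non-positive-definite covariance at
the current state raises an error naming the transform values.

Default chain settings mirror the source analysis (5,000,000 iterations,
100,000 burn-in, thinning 1,000). The `quick` preset (50,000 / 5,000 / 10,
4,500 retained samples) is the desk-scale configuration used throughout the
test suite and the acceptance script; the replicated recovery checks run 20
replicates of 150-tip trees at this preset. Seeds are mandatory for all
stochastic entry points; no clock seeding anywhere.

ML fits profile β and σ² in closed form at each transform value and
optimize the free transforms by L-BFGS-B from a small start grid. A
zero-residual fit pins σ² at 1e-12 and is flagged (logged) as degenerate.

## Marginal likelihoods

Marginal likelihoods are estimated by the harmonic mean of the chain's
likelihood samples, −log mean(exp(−logLᵢ)) via log-sum-exp, because that is
the estimator the original analysis used. The estimator is high-variance
and dominated by the smallest sampled likelihood; every call logs a
leave-out-the-minimum sensitivity so the instability is visible. Any
estimator with the same signature (e.g. stepping-stone) can replace it
behind `compare_models`. One chain per model feeds each estimate, with
independent sub-seeds spawned from the master seed. Log Bayes factors use
the 2Δ convention, which is the only simple convention that reproduces the
published arithmetic (harmonic means −46 vs −49 giving "a log Bayes factor
of six"; 1Δ would give three). The conventional >2 "positive evidence"
reading appears in logs only, never as pass/fail logic.

## Mk model and RJMCMC

The binary character evolves as a two-state CTMC with gain rate q01 and
loss rate q10; transition probabilities use the closed form. Likelihoods
use Felsenstein pruning with per-node rescaling; node marginals use the
standard up-down pass, validated against exhaustive enumeration on small
trees.

Root prior: stationary distribution of the current rate matrix
(BayesTraits-like); a uniform root is available and recorded in output.
Rate priors: q ~ Exponential(mean m) with m ~ Uniform(0, 10], interpreting
"hyperprior seeded from zero to ten" as a uniformly distributed exponential
mean that is itself resampled by the chain.

Reversible jump toggles between the equal-rates (q01 = q10) and two-rates
models with prior probability ½ each. The split move maps (q, u) →
(q eᵘ, q e⁻ᵘ) with u ~ N(0, s); the merge inverts it via the geometric
mean. The absolute Jacobian of (q, u) → (q01, q10) is 2q, which appears in
the acceptance ratio together with the proposal density of u (details in
code comments). Within-model moves are random walks on log rates (the q'/q
Jacobian included). Per-sample node marginals are averaged across retained
samples; node identity uses the sorted descendant-tip fingerprint, so
reports are stable under node reordering. `fixed_rates` disables all rate
moves (for validating the marginal computation); `rj=False` keeps the
fixed-dimension two-rate model.

## Synthetic data

The generators emulate the structure the analysis assumes: Yule (pure
birth) trees grown lineage-by-lineage with exponential waits and rescaled
to unit root-to-tip depth; traits drawn from MVN(Xβ, σ²C(λ,δ,κ)) via a
factorization of the transformed covariance; binary characters evolved
edge-by-edge with the closed-form transition matrix. All randomness flows
from one master seed through named sub-streams (tree / traits / mk).

Default truth values sit at the posterior means the packaged-data analysis
produces (β₁ = 3.24, β₂ = 0.88, λ = 0.88, κ = 0.14) so recovery tests probe
the empirically relevant region; σ² = 0.5 (no published value exists) gives
tip scatter comparable to ln femur residuals on a unit-depth tree. The
default predictor rule sets one internal clade (closest to 20% of tips) to
state 1, mimicking the clade-concentrated layout of the real character;
i.i.d. Bernoulli assignment is used for null-calibration tests. The
generators deliberately do not emulate fossil non-ultrametricity,
birth–death extinction, trait-dependent diversification, or measurement
error — passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to their
violation.

## Packaged data and stand-in tree

The 56-species table is transcribed at printed precision, guarded by a
checksum, and cross-checked in the suite against an independent second
transcription. Estimated femur lengths (Baryonyx, Buitreraptor) are
flagged. The morphological coding rules (caudal-only projections → 0, apex
flaring → 0, periosteal hook-like structures → 0, full-height or
margin-exceeding ligament metaplasia → 1) require specimen examination and
ship only as a documented vocabulary.

The analysis tree of the original study came from a published dinosaur
supertree and is not reproduced in the source; the packaged tree is a
synthetic stand-in (topology assembled from uncontroversial clade
memberships, Grafen clade-size branch lengths scaled to unit depth) named
and documented as such. Quantities that depend on that tree — the exact
posterior means, the harmonic means, per-node ancestral probabilities — are
therefore illustrative on the stand-in; the pipeline accepts any
user-supplied Newick/Nexus tree for an external check. Tree-independent
numbers (the published-table values, the 2Δ arithmetic) are exact.

## Known limitations

- The harmonic-mean marginal likelihood is kept for fidelity; treat its
  Bayes factors as noisy (the log output quantifies the instability).
- λ, δ, κ are bounded by configurable caps; fits at a cap are visible in
  the posterior summaries but not separately flagged.
- The regression models a single binary predictor; no multiple-predictor,
  logistic, or OU machinery is included.
- Mk ancestral states assume the tree is known without error; topological
  uncertainty is outside scope.
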