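# Methods

## Model

`jstdm` is a hierarchical multivariate GLMM over *column-units*: pairs
(species j, response type z).  With the case-study configuration the
response types are presence–absence (PA), abundance conditional on presence
(ABUC) and one type per site-level trait.  The linear predictor for site i
and column-unit c = (j, z) is

    L[i,c] = Σ_k X[i,k] B[k,c] + Σ_f H[i,f] Λ[f,c],

where X is the environmental design (intercept first) and H are latent
factor scores, a priori standard normal per site.  Observation families:

* PA columns: Bernoulli with probit link, y = 1{w > 0}, w ~ N(L, 1).
* All other columns: normal on the natural-log scale (log-normal on the
  original scale) with per-column residual variance σ²_c.

The hurdle decomposition makes ABUC and trait cells *structurally missing*
wherever PA = 0: a trait cannot be measured where the species does not
occur.  Missing cells are marginalized — skipped in every likelihood sum —
which is exact under conditional independence given (H, Λ) and avoids any
imputation bookkeeping.  A consequence used by the tests: chains are
bit-identical whatever values sit in unobserved cells.

The environmental responses are pooled through species-level traits.  Let
t_j be the trait row of species j (intercept plus log-scale species means)
and t̃_c its response-type expansion (t_j placed in the block of type z,
zeros elsewhere).  Then

    B[:,c] ~ N(Γ t̃_c, V),

so each trait effect in Γ is specific to a covariate, a trait and a response
type, and V is the covariance of species-specific deviations shared across
column-units.  The block expansion makes all per-type trait effects
estimable inside one conjugate multivariate regression.

Associations among column-units come from the loadings: Ω = ΛᵀΛ on the
covariance scale, scaled per draw to correlations.  Under the intercept-only
null model Ω captures raw associations; with covariates it captures residual
ones, and comparing the two classifies entries as retained / explained-away /
emergent.

## Sampler

All full conditionals are conjugate; one sweep updates, in order:

1. probit augmentation values (truncated normal at L, unit variance);
2. Γ (multivariate normal), V (inverse-Wishart), then each column's B
   (normal, precision V⁻¹ + X_oᵀX_o/σ²_c over observed rows);
3. H rows, Λ columns, then the shrinkage parameters;
4. σ²_c (inverse gamma over observed cells; PA columns pinned at 1).

Loadings carry the multiplicative gamma process prior: per-element
precisions ψ ~ Gamma(ν/2, ν/2) times cumulative column multipliers
τ_f = Π_{h≤f} δ_h, so later factors are shrunk progressively harder and a
fixed truncation is safe.  The factor count is fixed (default 5) rather than
adaptively birthed/killed: surplus factors simply vanish, and a fixed
truncation keeps runs reproducible.

Default priors (all overridable in `PriorConfig`, following the published
defaults of the HMSC model family): γ ~ N(0, 1) elementwise;
V ~ IW(n_c + 1, I); ν = 3, (a₁, b₁) = (50, 1), (a₂, b₂) = (50, 1);
σ² ~ InvGamma(1, 0.1).  `n_factors = 0` disables the factor block entirely,
which is how the closed-form regression oracle isolates the B update.

Numerical choices:

* Truncated-normal draws use the inverse-CDF with the inner probability
  clipped to [1e-14, 1−1e-14] and the result clamped to the truncation
  region, so the sign invariant is exact even at extreme linear predictors.
* Batched precision matrices are Cholesky-factorized; a non-positive-definite
  conditional covariance raises immediately rather than being silently
  regularized.
* The inverse-Wishart draw uses the Bartlett decomposition (validated
  against the analytic mean in the tests).
* Initialization: B from a ridge-stabilized (λ = 1e-3) per-column regression
  of the augmented responses on X; σ² from those residuals (floored at
  1e-3); H, Λ from N(0, 0.1²); augmentation values at ±√(2/π).  A
  rank-deficient X is an error.
* One master seed spawns independent per-chain streams
  (`numpy.random.SeedSequence`); spawned seeds are recorded in the output
  metadata, so every run is bit-reproducible.

Scaling: covariates and log-scale responses are centred and scaled to unit
variance by default (recorded and invertible) so the fixed prior scales are
sensible across datasets; predictions are issued back on the original
scales.  Log transforms use the natural log, and a non-positive observed
value is a hard error — the model has no pseudo-count, and silently adding
one would corrupt the log-normal likelihood.  Trait values observed where
the species is absent violate the hurdle data model and are an error by
default (a config switch downgrades them to masked-with-warning).  Column
order is species-major within response type (all PA columns, then all ABUC,
…), matching how association blocks are usually displayed; a stable
permutation to species-grouped order is provided.

Λ and H are left unidentified in sign and rotation; everything reported
(Ω, predictions, variance partitioning) is a rotation-invariant function,
and convergence diagnostics (split-chain R-hat, ESS via ArviZ) cover B, Γ
and Ω entries but deliberately not Λ or H.

## Prediction

* **Marginal**: fresh H ~ N(0, I) per draw and new site; PA columns map
  through Φ, log-normal columns back-transform as exp (posterior median) by
  default, with exp(· + σ²/2) (mean) available — the choice is inert for
  the predictive-correlation metric, which is computed on the log scale.
* **Conditional**: per posterior draw, a short inner Gibbs run (default 50
  sweeps after 20 discarded) alternates the new sites' factor scores with
  the probit augmentation of conditioned PA cells, holding conditioned
  values fixed; the final scores generate the prediction.  The run length
  was validated against the closed-form bivariate-normal conditioning
  oracle.  Per-site NaNs in the conditioning values leave those cells
  unconditioned, which is what lets a hurdle ABUC column (observed only
  where present) be conditioned on site by site.
* **Scenarios**: fixed covariate values (numeric or dataset quantiles,
  default 10%/90% for "low"/"high") and/or fixed focal-species columns;
  everything unset is marginalized; the focal species is excluded from the
  summary.  Expected richness is the per-draw sum of occurrence
  probabilities over non-focal species.

Variance partitioning follows the realized-design convention: the share of
covariate group g for a column is Σ_{k∈g} β_k (Sβ)_k with S the empirical
covariance of the fitted X, plus Σ_f λ²_f for the factors and σ² (or 1 for
probit) for the residual, normalized per draw.

## Cross-validation

Sites are split into k near-equal folds (sizes differ by at most one).
Baseline CV masks the full response vector of test sites and predicts
marginally; conditional CV conditions on the test sites' PA *and* ABUC
columns — abundance means both hurdle parts — and predicts the trait
columns.  Each fold refits on training sites only: scaling, species-level
traits and the fitted posterior all derive from training data, so held-out
values cannot leak (tested bit-exactly).  A species left without training
presences (or without any training trait value) is skipped for that fold
with a warning.  Performance is the signed Pearson correlation between
predicted and observed log values per species–trait combination (no
squaring: a negative correlation means worse-than-random and should stay
visible); combinations with fewer than 3 pairs or zero variance are
undefined, reported as missing rather than 0.  CV runs default to reduced
MCMC settings (4 chains × 4,000 iterations) with full-length overrides;
the settings used are recorded on the output table.

## Synthetic data

The generator draws from exactly the model above: trait effects with SD
`gamma_scale`, species deviations with covariance `beta_sd²·I`, loadings of
factor f with SD `lambda_scale · lambda_decay^f`, probit occurrence,
log-normal positive abundance (percent-cover-like continuous values) and
traits existing only where the species occurs.  Covariates are independent
standard normals: the model, not the covariate climatology, is under test.
Optionally the occurrence intercepts are calibrated so each species'
expected prevalence is a log-uniform draw from a given range, accounting for
that column's covariate and factor variance.

`case_study_fixture` mirrors the tundra design: 325 sites, 65 species,
response types (PA, ABUC, SLA, LA, MH), covariates GDD/FDD/SM, prevalence
range (0.16, 0.58) — median ≈ 0.3 and every species safely above the
25-site filter — with moderate effect scales (γ SD 0.3, deviation SD 0.3,
loading SD 0.6 with decay 0.6 over 3 factors, residual SD 0.6).

What passing on synthetic data does and does not show: the generator has no
covariate collinearity, no spatial or phylogenetic structure, no
measurement error beyond the model's own residuals and no model
misspecification, so recovery and CV results certify the inference
machinery, not robustness to the ways real community data deviate from the
model.

## Problem sizes used in tests and the acceptance script

Parameter recovery uses 200 sites, 20 species, 3 response types
(PA + ABUC + one trait), 2 covariates and 2 factors, fit with 2 chains ×
4,000 iterations (1,000 burn-in, thin 10), median over 5 seeds — small
enough to run routinely, large enough that true-vs-posterior-mean
correlations are stable.  The CV comparison uses 120 sites, 10 species,
3 folds and 2 chains × 1,500 iterations per fold, 5 seeds per condition,
with loading SD 0.9 against residual SD 0.5 in the linked condition and
zero loadings in the null condition.  The retained-draw arithmetic is
checked at the full 4 × 37,500 / 12,500 / thin-100 schedule on a minimal
design.

## Known limitations

* No phylogenetic, spatial or temporal random effects; no adaptive factor
  truncation.
* Whether per-site trait averaging (before the model sees the data) happens
  on the natural or log scale is the data collector's choice; the package
  accepts pre-averaged site-level values and derives species-level traits
  as means of observed site-level *log* values.
* Conditional prediction assumes the conditioned columns' parameters come
  from the same fitted posterior; conditioning on values far outside the
  training range extrapolates.
* The probit augmentation clamps extreme tails (see above); effects are
  far below statistical noise at realistic linear-predictor ranges.
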