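# jstdm — joint species–trait distribution modelling

`jstdm` fits Bayesian joint models of species communities in which every
species contributes **several response columns**: its presence–absence (PA),
its abundance conditional on presence (ABUC, the positive part of a hurdle
model) and one column per site-level trait (e.g. specific leaf area, leaf
area, vegetative height).  Stacking abundances and intraspecific trait values
into one multiresponse matrix lets a single model estimate

* how environmental covariates drive occurrence, abundance **and** site-level
  trait variation,
* how those environmental responses are mediated by species-level traits, and
* the residual associations among all abundance and trait columns — e.g.
  whether neighbours carry systematically larger leaves where a focal species
  is abundant.

It is aimed at community ecologists with sites × species abundance tables,
per-trait sites × species tables (missing where the species is absent) and a
sites × covariates table.

## The model

For site *i* and column-unit *c = (j, z)* (species *j*, response type *z*),
the linear predictor is

```
L[i,jz] = Σ_k x[i,k] β[k,jz]  +  Σ_f η[i,f] λ[f,jz]
```

with latent factor scores η ~ N(0, I) and loadings λ under a multiplicative
gamma process shrinkage prior.  PA columns observe `y = 1{L + ε > 0}`
(probit, via truncated-normal augmentation); all other columns are log-normal
with residual variance σ²ₖ.  The environmental responses are tied across
column-units through species-level traits t (averages across sites):

```
E(β[k,jz]) = Σ_l t[j,l] γ[k,l,z],        β·,jz ~ N(Γ t̃_jz, V)
```

so γ estimates, per response type, how species-level traits shape
environmental responses — including the response of site-level traits
themselves.  The loadings induce the association matrix

```
Ω[j1z1, j2z2] = Σ_f λ[f,j1z1] λ[f,j2z2]
```

which is "raw" under an intercept-only null model and "residual" once
covariates are included; entries are called positive/negative when their
posterior probability of that sign reaches 90%.  Trait and ABUC cells are
structurally missing where the species is absent and are marginalized, never
imputed.  Inference is a fully conjugate blocked Gibbs sampler.

Built on top of the posterior:

* **Conditional prediction** — predict a site's trait columns given its
  observed PA/ABUC columns (the engine behind conditional cross-validation
  and trait imputation).
* **Scenario simulation** — fix covariates and/or a focal species' columns,
  marginalize the rest, and summarize the community as expected richness
  (the sum of occurrence probabilities).
* **Cross-validation** — baseline (all responses masked) vs conditional
  (abundances kept) k-fold CV, scored by the signed Pearson correlation per
  species–trait pair.

## Worked example

```python
import numpy as np
from jstdm import (PriorConfig, build_design, run_mcmc, association_matrix,
                   predict_conditional, generate_parameters, generate_community)

truth = generate_parameters(n_species=8, n_traits=1, n_covariates=2,
                            n_factors=2, prevalence_range=(0.25, 0.7), seed=11)
abundance, traits, covariates = generate_community(truth, 100, seed=12)
design = build_design(abundance, traits, covariates)
print(design.Y.n_cols)                       # 24 column-units = 8 species x 3 types

samples = run_mcmc(design, PriorConfig(n_factors=2), chains=2,
                   iterations=600, burn_in=200, thin=4, seed=21)
print(samples.n_total)                       # 200 retained posterior draws

assoc = association_matrix(samples, labels=design.Y.column_labels)
support = assoc.support(0.90)
print(int(np.nansum(np.abs(support))))       # 326 entries with >= 90% support

sp = design.Y.species[0]
cond = predict_conditional(samples, design, covariates.iloc[:1],
                           {(sp, "PA"): 1.0, (sp, "ABUC"): 5.0}, seed=0)
print(round(float(cond.mean_response[0, design.Y.col_index(sp, "T1")]), 2))  # 0.88
```

The first two numbers are design arithmetic (column-unit count, retained
draws).  The support count says how many association-matrix entries have at
least 90% posterior probability of a definite sign on this synthetic
community, and the last line is the predicted natural-scale trait value for
species `sp001` at a site where it is present with abundance 5 — the
conditional-prediction path that imputes traits from abundance data.

There is also a CLI covering the same workflow:
`jstdm simulate | fit | associations | predict | cv | diagnostics`
(see `jstdm --help`).

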