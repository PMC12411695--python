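"""Synthetic communities drawn from the exact generative model.

The generator mirrors the fitted model: environmental responses tied to
species-level traits, latent factors with decaying loading scales generating
trait-abundance covariance, a probit hurdle for occurrence, log-normal
positive abundance and site-level traits, and structural missingness (trait
and conditional-abundance cells exist only where the species occurs).
Covariates are simulated as independent standard normals: the model, not the
covariate climatology, is under test.  Abundance is generated as a positive
continuous (percent-cover-like) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from .design import (
    ModelDesign,
    SpeciesTraitMatrix,
    build_design,
    expand_trait_design,
)
from .responses import ResponseType, case_study_rtypes, validate_rtypes

__all__ = [
    "TruthBundle",
    "SyntheticCommunity",
    "generate_parameters",
    "generate_community",
    "case_study_fixture",
]


@dataclass
class TruthBundle:
    """True parameter values behind a synthetic community."""

    species: list[str]
    trait_names: list[str]
    rtypes: list[ResponseType]
    covariate_names: list[str]
    T: np.ndarray          # n_species x (1 + n_traits), intercept first, log scale
    gamma: np.ndarray      # n_c x q
    V: np.ndarray          # n_c x n_c
    beta: np.ndarray       # n_c x n_cols
    Lambda: np.ndarray     # n_f x n_cols
    sigma2: np.ndarray     # n_cols (1.0 on probit columns)
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_rtypes(self) -> int:
        return len(self.rtypes)

    @property
    def n_cols(self) -> int:
        return self.n_species * self.n_rtypes

    @property
    def n_factors(self) -> int:
        return self.Lambda.shape[0]

    @property
    def is_probit(self) -> np.ndarray:
        return np.repeat([r.is_probit for r in self.rtypes], self.n_species)

    @property
    def omega_cov(self) -> np.ndarray:
        return self.Lambda.T @ self.Lambda

    @property
    def omega_corr(self) -> np.ndarray:
        cov = self.omega_cov
        d = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            return cov / np.outer(d, d)

    def block_slice(self, rtype_name: str) -> slice:
        z = [r.name for r in self.rtypes].index(rtype_name)
        return slice(z * self.n_species, (z + 1) * self.n_species)


def generate_parameters(
    n_species: int = 20,
    n_traits: int = 1,
    rtypes: Sequence[ResponseType] | None = None,
    n_covariates: int = 2,
    n_factors: int = 2,
    gamma_scale: float = 0.5,
    beta_sd: float = 0.3,
    lambda_scale: float = 0.8,
    lambda_decay: float = 0.6,
    sigma: float = 0.5,
    prevalence_range: tuple[float, float] | None = None,
    seed: int | None = None,
    species: Sequence[str] | None = None,
    covariate_names: Sequence[str] | None = None,
) -> TruthBundle:
    """Draw a true parameter bundle from the generative hierarchy.

    Trait effects have SD ``gamma_scale``; species deviations of the
    environmental responses have covariance ``beta_sd**2 I``; loadings of
    factor f have SD ``lambda_scale * lambda_decay**f``.  If
    ``prevalence_range=(lo, hi)`` is given, occurrence intercepts are set so
    each species' expected prevalence is a log-uniform draw from [lo, hi]
    (accounting for the covariate and factor variance at that column).
    """
    rng = np.random.default_rng(seed)
    if rtypes is None:
        trait_names = [f"T{i+1}" for i in range(n_traits)]
        rtypes = case_study_rtypes(trait_names)
    else:
        rtypes = list(rtypes)
        trait_names = [r.name for r in rtypes if r.role == "trait"]
    validate_rtypes(rtypes)
    if species is None:
        species = [f"sp{j+1:03d}" for j in range(n_species)]
    species = list(species)
    n_species = len(species)
    if covariate_names is None:
        covariate_names = [f"x{k+1}" for k in range(n_covariates)]
    covariate_names = list(covariate_names)
    n_c = 1 + len(covariate_names)
    n_z = len(rtypes)
    n_cols = n_species * n_z

    T = np.column_stack([np.ones(n_species), rng.standard_normal((n_species, len(trait_names)))])
    stm = SpeciesTraitMatrix(T, trait_names, species)
    Ttilde = expand_trait_design(stm, rtypes).values

    q = Ttilde.shape[1]
    gamma = gamma_scale * rng.standard_normal((n_c, q))
    V = beta_sd**2 * np.eye(n_c)
    beta = gamma @ Ttilde.T + beta_sd * rng.standard_normal((n_c, n_cols))
    scales = lambda_scale * lambda_decay ** np.arange(n_factors)
    Lambda = scales[:, None] * rng.standard_normal((n_factors, n_cols))
    is_probit = np.repeat([r.is_probit for r in rtypes], n_species)
    sigma2 = np.where(is_probit, 1.0, sigma**2)

    occ = [r for r in rtypes if r.role == "occurrence"]
    if prevalence_range is not None and occ:
        lo, hi = prevalence_range
        p = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_species))
        blk = slice(
            [r.name for r in rtypes].index(occ[0].name) * n_species,
            ([r.name for r in rtypes].index(occ[0].name) + 1) * n_species,
        )
        extra_var = np.sum(beta[1:, blk] ** 2, axis=0) + np.sum(Lambda[:, blk] ** 2, axis=0)
        beta[0, blk] = special.ndtri(p) * np.sqrt(1.0 + extra_var)

    return TruthBundle(
        species=species,
        trait_names=list(trait_names),
        rtypes=rtypes,
        covariate_names=covariate_names,
        T=T,
        gamma=gamma,
        V=V,
        beta=beta,
        Lambda=Lambda,
        sigma2=sigma2,
        seed=seed,
        settings={
            "gamma_scale": gamma_scale, "beta_sd": beta_sd,
            "lambda_scale": lambda_scale, "lambda_decay": lambda_decay,
            "sigma": sigma, "prevalence_range": prevalence_range,
        },
    )


def generate_community(
    truth: TruthBundle, n_sites: int, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate one community: abundance, trait and covariate tables.

    Occurrence is a probit draw on the linear predictor; positive abundance
    and trait values are log-normal around theirs and exist only where the
    species occurs (structural missingness of the hurdle).
    """
    rng = np.random.default_rng(seed)
    site_ids = [f"site{i+1:04d}" for i in range(n_sites)]
    Xc = rng.standard_normal((n_sites, len(truth.covariate_names)))
    X = np.column_stack([np.ones(n_sites), Xc])
    H = rng.standard_normal((n_sites, truth.n_factors))
    L = X @ truth.beta + H @ truth.Lambda
    noise = rng.standard_normal(L.shape) * np.sqrt(truth.sigma2)[None, :]
    latent = L + noise

    occ = [r for r in truth.rtypes if r.role == "occurrence"]
    abu = [r for r in truth.rtypes if r.role == "abundance"]
    if occ:
        present = latent[:, truth.block_slice(occ[0].name)] > 0
    else:
        present = np.ones((n_sites, truth.n_species), dtype=bool)

    if abu:
        ab_latent = np.exp(latent[:, truth.block_slice(abu[0].name)])
        abundance = np.where(present, ab_latent, 0.0)
    else:
        abundance = present.astype(float)
    abundance_df = pd.DataFrame(abundance, index=site_ids, columns=truth.species)

    trait_dfs = {}
    for r in truth.rtypes:
        if r.role != "trait":
            continue
        vals = np.exp(latent[:, truth.block_slice(r.name)])
        trait_dfs[r.name] = pd.DataFrame(
            np.where(present, vals, np.nan), index=site_ids, columns=truth.species
        )
    cov_df = pd.DataFrame(Xc, index=site_ids, columns=truth.covariate_names)
    return abundance_df, trait_dfs, cov_df


@dataclass
class SyntheticCommunity:
    """A generated dataset plus the truth that generated it."""

    truth: TruthBundle
    abundance: pd.DataFrame
    trait_tables: dict[str, pd.DataFrame]
    covariates: pd.DataFrame

    def to_design(self, **kwargs) -> ModelDesign:
        kwargs.setdefault("rtypes", self.truth.rtypes)
        return build_design(self.abundance, self.trait_tables, self.covariates, **kwargs)


def case_study_fixture(seed: int | None = 0) -> SyntheticCommunity:
    """A case-study-shaped synthetic community.

    325 sites, 65 species, response types (PA, ABUC, SLA, LA, MH) and three
    covariates named GDD, FDD and SM; occurrence intercepts calibrated so
    the median expected prevalence is near 0.3 and every species comfortably
    clears a 25-site prevalence filter.  The assembled matrix has
    65 × 5 = 325 column-units.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    truth = generate_parameters(
        n_species=65,
        rtypes=case_study_rtypes(("SLA", "LA", "MH")),
        n_covariates=3,
        n_factors=3,
        gamma_scale=0.3,
        beta_sd=0.3,
        lambda_scale=0.6,
        lambda_decay=0.6,
        sigma=0.6,
        prevalence_range=(0.16, 0.58),
        seed=s1,
        covariate_names=["GDD", "FDD", "SM"],
    )
    abundance, traits, cov = generate_community(truth, 325, seed=s2)
    return SyntheticCommunity(truth, abundance, traits, cov)
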