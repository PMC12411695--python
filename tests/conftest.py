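import numpy as np
import pandas as pd
import pytest

from jstdm.design import (
    EnvironmentalDesign,
    ModelDesign,
    MultiResponseMatrix,
    SpeciesTraitMatrix,
    build_design,
    expand_trait_design,
)
from jstdm.priors import PriorConfig
from jstdm.responses import ResponseType
from jstdm.sampler import run_mcmc
from jstdm.synthetic import generate_community, generate_parameters


def lognormal_design(n_sites: int, n_types: int, species=("s1",), seed=0):
    """Hand-built all-lognormal design (no hurdle) for conjugate oracle tests.

    Values are standard-normal placeholders on the model scale; tests that
    need specific responses overwrite ``design.Y.values``.
    """
    rng = np.random.default_rng(seed)
    rtypes = [ResponseType(f"T{i+1}", "lognormal", "log", "trait") for i in range(n_types)]
    n_cols = n_types * len(species)
    Y = MultiResponseMatrix(
        rng.standard_normal((n_sites, n_cols)),
        np.ones((n_sites, n_cols), dtype=bool),
        list(range(n_sites)),
        list(species),
        rtypes,
        np.zeros(n_cols),
        np.ones(n_cols),
    )
    env = EnvironmentalDesign.intercept_only(Y.site_ids)
    T = SpeciesTraitMatrix.intercept_only(Y.species)
    return ModelDesign(Y, env, T, expand_trait_design(T, rtypes))


@pytest.fixture(scope="session")
def small_truth():
    return generate_parameters(
        n_species=8, n_traits=1, n_covariates=2, n_factors=2,
        prevalence_range=(0.25, 0.7), seed=11,
    )


@pytest.fixture(scope="session")
def small_tables(small_truth):
    return generate_community(small_truth, 100, seed=12)


@pytest.fixture(scope="session")
def small_design(small_tables):
    ab, traits, cov = small_tables
    return build_design(ab, traits, cov)


@pytest.fixture(scope="session")
def small_fit(small_design):
    """A quick 2-chain fit shared by association/prediction/diagnostic tests."""
    return run_mcmc(
        small_design, PriorConfig(n_factors=2),
        chains=2, iterations=600, burn_in=200, thin=4, seed=21,
    )
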