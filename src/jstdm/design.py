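"""Data model: multiresponse matrix, environmental design, trait design.

Assembly turns the three user-facing tables (sites × species abundances,
per-trait sites × species values, sites × covariates) into the internal model
objects:

* :class:`MultiResponseMatrix` — Y over column-units, hurdle structure encoded
  as a missingness mask (abundance-conditional and trait cells are unobserved
  exactly where the species is absent), log-normal columns stored on the
  (optionally centred/scaled) natural-log scale.
* :class:`EnvironmentalDesign` — X with an intercept column and an invertible
  centring/scaling record.
* :class:`SpeciesTraitMatrix` and its response-type expansion
  :class:`TraitDesignExpanded`, which makes the per-type trait effects
  estimable within a single trait regression.

Column ordering is species-major within response type: all occurrence columns
first (species in input order), then all abundance columns, then each trait
block.  ``species_block_permutation`` gives the stable permutation to the
species-major (all columns of species 1, then species 2, ...) layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .responses import ColumnUnit, ResponseType, case_study_rtypes, validate_rtypes

__all__ = [
    "MultiResponseMatrix",
    "EnvironmentalDesign",
    "SpeciesTraitMatrix",
    "TraitDesignExpanded",
    "ModelDesign",
    "assemble_multiresponse",
    "filter_by_prevalence",
    "expand_trait_design",
    "species_level_traits_from_sites",
    "build_design",
]

logger = logging.getLogger(__name__)


@dataclass
class MultiResponseMatrix:
    """Sites × column-units response matrix Y with per-cell observation mask.

    ``values`` holds occurrence cells in {0, 1} and log-normal cells on the
    model (centred/scaled log) scale; unobserved cells hold NaN and are never
    read by the sampler.  ``col_center``/``col_scale`` record the affine map
    from the natural-log scale to the model scale (0/1 for occurrence
    columns), so predictions can be issued on the original scales.
    """

    values: np.ndarray
    observed: np.ndarray
    site_ids: list
    species: list[str]
    rtypes: list[ResponseType]
    col_center: np.ndarray
    col_scale: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must share a shape")
        if self.values.shape != (self.n_sites, self.n_cols):
            raise ValueError(
                f"expected shape {(self.n_sites, self.n_cols)}, got {self.values.shape}"
            )
        if np.any(~np.isfinite(self.values) & self.observed):
            raise ValueError("non-finite value flagged as observed")

    # -- indexing -----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

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
    def column_units(self) -> list[ColumnUnit]:
        return [ColumnUnit(j, z) for z in self.rtypes for j in self.species]

    @property
    def column_labels(self) -> list[str]:
        return [cu.label for cu in self.column_units]

    def col_index(self, species: str, rtype_name: str) -> int:
        z = [r.name for r in self.rtypes].index(rtype_name)
        j = self.species.index(species)
        return z * self.n_species + j

    def block_slice(self, rtype_name: str) -> slice:
        z = [r.name for r in self.rtypes].index(rtype_name)
        return slice(z * self.n_species, (z + 1) * self.n_species)

    def col_rtype(self, c: int) -> ResponseType:
        return self.rtypes[c // self.n_species]

    @property
    def is_probit(self) -> np.ndarray:
        """Boolean per-column flag: True for occurrence (probit) columns."""
        return np.repeat([r.is_probit for r in self.rtypes], self.n_species)

    def species_block_permutation(self) -> np.ndarray:
        """Permutation to species-major layout (all columns of species 1 first)."""
        idx = np.arange(self.n_cols).reshape(self.n_rtypes, self.n_species)
        return idx.T.ravel()

    # -- manipulation -------------------------------------------------------
    def mask_sites(self, site_ids: Sequence, rtype_names: Sequence[str] | None = None) -> "MultiResponseMatrix":
        """Return a copy with the given sites' cells marked unobserved.

        ``rtype_names`` restricts masking to those response types (default:
        every column) — the primitive behind baseline vs. conditional
        cross-validation.
        """
        rows = [self.site_ids.index(s) for s in site_ids]
        observed = self.observed.copy()
        values = self.values.copy()
        if rtype_names is None:
            cols = np.arange(self.n_cols)
        else:
            cols = np.concatenate(
                [np.arange(self.n_cols)[self.block_slice(n)] for n in rtype_names]
            )
        observed[np.ix_(rows, cols)] = False
        values[~observed] = np.nan
        return replace(self, values=values, observed=observed)

    def disassemble(self) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
        """Reverse assembly: abundance table and per-trait tables on natural scales."""
        occ = [r for r in self.rtypes if r.role == "occurrence"]
        ab = [r for r in self.rtypes if r.role == "abundance"]
        log_vals = self.col_center + self.col_scale * np.where(self.observed, self.values, np.nan)
        abundance = pd.DataFrame(
            np.zeros((self.n_sites, self.n_species)), index=self.site_ids, columns=self.species
        )
        if occ:
            pa = self.values[:, self.block_slice(occ[0].name)]
            if ab:
                abu = np.exp(log_vals[:, self.block_slice(ab[0].name)])
                abundance[:] = np.where(pa > 0, abu, 0.0)
            else:
                abundance[:] = pa
        traits: dict[str, pd.DataFrame] = {}
        for r in self.rtypes:
            if r.role == "trait":
                traits[r.name] = pd.DataFrame(
                    np.exp(log_vals[:, self.block_slice(r.name)]),
                    index=self.site_ids,
                    columns=self.species,
                )
        return abundance, traits


@dataclass
class EnvironmentalDesign:
    """Sites × covariates design X: intercept first, invertible scaling record."""

    X: np.ndarray
    covariate_names: list[str]
    site_ids: list
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be a constant intercept")

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_table(
        cls, covariates: pd.DataFrame, scale: bool = True
    ) -> "EnvironmentalDesign":
        vals = covariates.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("covariate table contains non-finite values")
        if scale and len(covariates) > 1:
            center = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=0)
            if np.any(sd == 0):
                bad = [c for c, s in zip(covariates.columns, sd) if s == 0]
                raise ValueError(f"constant covariate(s) cannot be scaled: {bad}")
        else:
            center = np.zeros(vals.shape[1])
            sd = np.ones(vals.shape[1])
        X = np.column_stack([np.ones(len(covariates)), (vals - center) / sd])
        return cls(X, list(covariates.columns), list(covariates.index), center, sd)

    @classmethod
    def intercept_only(cls, site_ids: Sequence) -> "EnvironmentalDesign":
        """Null-model design: intercept column only."""
        return cls(
            np.ones((len(site_ids), 1)), [], list(site_ids), np.zeros(0), np.ones(0)
        )

    def transform(self, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Map new original-scale covariates onto the fitted design scale."""
        if isinstance(covariates, pd.DataFrame):
            missing = [c for c in self.covariate_names if c not in covariates.columns]
            if missing:
                raise ValueError(f"missing covariate column(s): {missing}")
            vals = covariates[self.covariate_names].to_numpy(dtype=float)
        else:
            vals = np.asarray(covariates, dtype=float).reshape(-1, len(self.covariate_names))
        return np.column_stack([np.ones(len(vals)), (vals - self.center) / self.scale])

    def original_scale(self) -> np.ndarray:
        """Covariate values (no intercept) back on their original scales."""
        return self.X[:, 1:] * self.scale + self.center


@dataclass
class SpeciesTraitMatrix:
    """Species-level trait matrix T: intercept column plus log-scale traits.

    ``provenance`` records whether values were supplied directly or derived as
    per-species means of observed site-level (log) values.
    """

    T: np.ndarray
    trait_names: list[str]
    species: list[str]
    provenance: str = "supplied"
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (len(self.species), 1 + len(self.trait_names)):
            raise ValueError("T must be species × (1 + n_traits) with intercept first")
        if not np.allclose(self.T[:, 0], 1.0):
            raise ValueError("first trait column must be a constant intercept")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @classmethod
    def intercept_only(cls, species: Sequence[str]) -> "SpeciesTraitMatrix":
        return cls(np.ones((len(species), 1)), [], list(species), "supplied")

    def subset(self, species: Sequence[str]) -> "SpeciesTraitMatrix":
        rows = [self.species.index(s) for s in species]
        return replace(self, T=self.T[rows], species=list(species))


@dataclass
class TraitDesignExpanded:
    """Response-type expansion T̃ of the species-level trait matrix.

    Row (j, z) carries the trait row of species j in the block of response
    type z and zeros elsewhere, so the per-type trait effects form a single
    stacked coefficient vector.  Rows follow the multiresponse column order.
    """

    values: np.ndarray
    rtypes: list[ResponseType]
    trait_matrix: SpeciesTraitMatrix

    @property
    def n_block(self) -> int:
        return self.trait_matrix.T.shape[1]

    def block_collapse(self) -> np.ndarray:
        """Recover T from any single response-type block (bit-exact)."""
        n_s = len(self.trait_matrix.species)
        return self.values[:n_s, : self.n_block]


def expand_trait_design(
    T: SpeciesTraitMatrix, rtypes: Sequence[ResponseType]
) -> TraitDesignExpanded:
    """Place each species' trait row in its response type's column block."""
    validate_rtypes(rtypes)
    n_s, n_b = T.T.shape
    n_z = len(rtypes)
    out = np.zeros((n_z * n_s, n_z * n_b))
    for z in range(n_z):
        out[z * n_s : (z + 1) * n_s, z * n_b : (z + 1) * n_b] = T.T
    return TraitDesignExpanded(out, list(rtypes), T)


def species_level_traits_from_sites(
    trait_tables: Mapping[str, pd.DataFrame],
    species: Sequence[str] | None = None,
    scale: bool = True,
) -> SpeciesTraitMatrix:
    """Derive species-level traits as per-species means of site-level log values.

    Trait tables hold natural-scale positive values with missing cells where
    the species is absent.  Averaging is done on the natural-log scale (the
    model scale); the result is optionally centred/scaled per trait with the
    record kept for inverse mapping.
    """
    names = list(trait_tables)
    first = trait_tables[names[0]]
    if species is None:
        species = list(first.columns)
    cols = []
    for name in names:
        tab = trait_tables[name]
        # contiguous copy: summation order (and hence the derived means) must
        # not depend on the caller's DataFrame memory layout
        vals = np.ascontiguousarray(tab[list(species)].to_numpy(dtype=float))
        obs = np.isfinite(vals)
        if np.any(vals[obs] <= 0):
            raise ValueError(f"non-positive observed value in trait table {name!r}")
        counts = obs.sum(axis=0)
        if np.any(counts == 0):
            bad = [s for s, c in zip(species, counts) if c == 0]
            raise ValueError(f"species with no observed {name!r} values: {bad}")
        logv = np.where(obs, np.log(np.where(obs, vals, 1.0)), 0.0)
        cols.append(logv.sum(axis=0) / counts)
    T = np.array(cols).T  # species × traits
    if scale and len(species) > 1:
        center = T.mean(axis=0)
        sd = T.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        T = (T - center) / sd
    else:
        center = np.zeros(T.shape[1])
        sd = np.ones(T.shape[1])
    T = np.column_stack([np.ones(len(species)), T])
    return SpeciesTraitMatrix(T, names, list(species), "derived", center, sd)


def assemble_multiresponse(
    abundance_table: pd.DataFrame,
    trait_tables: Mapping[str, pd.DataFrame],
    rtypes: Sequence[ResponseType] | None = None,
    scale_responses: bool = True,
    on_trait_without_presence: str = "error",
) -> MultiResponseMatrix:
    """Assemble the multiresponse matrix from abundance and trait tables.

    The hurdle decomposition sets the occurrence column to 1(abundance > 0),
    the abundance-conditional column to log(abundance) where positive (else
    unobserved) and each trait column to log(trait) where present (else
    unobserved).  A trait value observed where the species is absent violates
    the hurdle data model and is a hard error unless
    ``on_trait_without_presence="mask"``.
    """
    if rtypes is None:
        rtypes = case_study_rtypes(tuple(trait_tables))
    rtypes = list(rtypes)
    validate_rtypes(rtypes)
    species = list(abundance_table.columns)
    site_ids = list(abundance_table.index)
    for name, tab in trait_tables.items():
        if list(tab.index) != site_ids or list(tab.columns) != species:
            raise ValueError(f"trait table {name!r} indexes do not match abundance table")
    trait_rtypes = [r for r in rtypes if r.role == "trait"]
    missing_tables = [r.name for r in trait_rtypes if r.name not in trait_tables]
    if missing_tables:
        raise ValueError(f"no trait table supplied for response type(s) {missing_tables}")
    abund = np.ascontiguousarray(abundance_table.to_numpy(dtype=float))
    if np.any(~np.isfinite(abund)) or np.any(abund < 0):
        raise ValueError("abundance table must be finite and non-negative")
    present = abund > 0

    n_s, n_z = len(species), len(rtypes)
    values = np.full((len(site_ids), n_s * n_z), np.nan)
    observed = np.zeros_like(values, dtype=bool)
    for z, r in enumerate(rtypes):
        blk = slice(z * n_s, (z + 1) * n_s)
        if r.role == "occurrence":
            values[:, blk] = present.astype(float)
            observed[:, blk] = True
        elif r.role == "abundance":
            values[:, blk] = np.where(present, np.log(np.where(present, abund, 1.0)), np.nan)
            observed[:, blk] = present
        else:
            tab = np.ascontiguousarray(trait_tables[r.name].to_numpy(dtype=float))
            obs = np.isfinite(tab)
            bad = obs & (tab <= 0)
            if np.any(bad):
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-positive trait value in {r.name!r} at site {site_ids[i]!r}, "
                    f"species {species[j]!r}: log is undefined"
                )
            orphan = obs & ~present
            if np.any(orphan):
                i, j = np.argwhere(orphan)[0]
                msg = (
                    f"trait {r.name!r} observed where species is absent "
                    f"(site {site_ids[i]!r}, species {species[j]!r})"
                )
                if on_trait_without_presence == "error":
                    raise ValueError(msg + "; pass on_trait_without_presence='mask' to drop")
                logger.warning("%s; masking %d cell(s)", msg, int(orphan.sum()))
                obs = obs & present
            values[:, blk] = np.where(obs, np.log(np.where(obs, tab, 1.0)), np.nan)
            observed[:, blk] = obs

    # centring/scaling of log-normal columns on observed cells
    col_center = np.zeros(n_s * n_z)
    col_scale = np.ones(n_s * n_z)
    if scale_responses:
        for z, r in enumerate(rtypes):
            if r.is_probit:
                continue
            blk = slice(z * n_s, (z + 1) * n_s)
            v, m = values[:, blk], observed[:, blk]
            cnt = m.sum(axis=0)
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, np.nansum(np.where(m, v, np.nan), axis=0) / np.maximum(cnt, 1), 0.0)
                sq = np.nansum(np.where(m, (v - mean) ** 2, np.nan), axis=0)
                sd = np.sqrt(np.where(cnt > 1, sq / np.maximum(cnt, 1), 1.0))
            sd = np.where((cnt > 1) & (sd > 0), sd, 1.0)
            col_center[blk] = np.where(cnt > 0, mean, 0.0)
            col_scale[blk] = sd
            values[:, blk] = np.where(m, (v - mean) / sd, np.nan)

    return MultiResponseMatrix(values, observed, site_ids, species, rtypes, col_center, col_scale)


def filter_by_prevalence(M: MultiResponseMatrix, min_sites: int) -> MultiResponseMatrix:
    """Retain species whose occurrence column sums to at least ``min_sites``."""
    if min_sites > M.n_sites:
        raise ValueError("min_sites exceeds the number of sites")
    occ = [r for r in M.rtypes if r.role == "occurrence"]
    if not occ:
        raise ValueError("prevalence filter requires an occurrence response type")
    pa = M.values[:, M.block_slice(occ[0].name)]
    prevalence = pa.sum(axis=0)
    keep = prevalence >= min_sites
    if not np.any(keep):
        raise ValueError(f"prevalence filter {min_sites} removed every species")
    kept = [s for s, k in zip(M.species, keep) if k]
    logger.info("prevalence filter >= %d sites: kept %d/%d species", min_sites, len(kept), M.n_species)
    col_keep = np.tile(keep, M.n_rtypes)
    return MultiResponseMatrix(
        M.values[:, col_keep],
        M.observed[:, col_keep],
        M.site_ids,
        kept,
        M.rtypes,
        M.col_center[col_keep],
        M.col_scale[col_keep],
    )


@dataclass
class ModelDesign:
    """Bundle consumed by the sampler: Y, X and the expanded trait design."""

    Y: MultiResponseMatrix
    env: EnvironmentalDesign
    traits: SpeciesTraitMatrix
    Ttilde: TraitDesignExpanded

    def __post_init__(self) -> None:
        if self.Ttilde.values.shape[0] != self.Y.n_cols:
            raise ValueError("trait design rows must match response columns")
        if self.env.X.shape[0] != self.Y.n_sites:
            raise ValueError("environmental design rows must match sites")

    @property
    def n_sites(self) -> int:
        return self.Y.n_sites

    @property
    def n_cols(self) -> int:
        return self.Y.n_cols


def build_design(
    abundance_table: pd.DataFrame,
    trait_tables: Mapping[str, pd.DataFrame],
    covariates: pd.DataFrame | None,
    rtypes: Sequence[ResponseType] | None = None,
    min_prevalence: int = 0,
    scale_responses: bool = True,
    scale_covariates: bool = True,
    species_traits: SpeciesTraitMatrix | None = None,
    null_model: bool = False,
    on_trait_without_presence: str = "error",
) -> ModelDesign:
    """Full assembly pipeline: multiresponse matrix, prevalence filter, designs.

    ``null_model=True`` builds the intercept-only model (no covariates, no
    species-level traits), the reference against which residual associations
    are compared.
    """
    Y = assemble_multiresponse(
        abundance_table,
        trait_tables,
        rtypes,
        scale_responses=scale_responses,
        on_trait_without_presence=on_trait_without_presence,
    )
    if min_prevalence:
        Y = filter_by_prevalence(Y, min_prevalence)
    if null_model or covariates is None:
        env = EnvironmentalDesign.intercept_only(Y.site_ids)
    else:
        if list(covariates.index) != Y.site_ids:
            raise ValueError("covariate table sites do not match abundance table")
        env = EnvironmentalDesign.from_table(covariates, scale=scale_covariates)
    if null_model:
        T = SpeciesTraitMatrix.intercept_only(Y.species)
    elif species_traits is not None:
        T = species_traits.subset(Y.species)
    elif trait_tables:
        sub = {k: v[Y.species] for k, v in trait_tables.items()}
        T = species_level_traits_from_sites(sub, Y.species)
    else:
        T = SpeciesTraitMatrix.intercept_only(Y.species)
    Tt = expand_trait_design(T, Y.rtypes)
    return ModelDesign(Y, env, T, Tt)
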