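"""Posterior prediction: marginal, conditional and scenario simulation.

Marginal prediction integrates over fresh latent factor scores (new sites
are exchangeable draws from the factor prior).  Conditional prediction is
the engine behind conditional cross-validation and focal-species scenarios:
for each posterior draw a short inner Gibbs run samples the new sites'
factor scores given whichever column values are held fixed (occurrence cells
through their probit augmentation), and the remaining columns are predicted
from the resulting scores.  Fixing nothing recovers marginal prediction in
distribution; fixing values on columns that share loadings with the target
moves the target prediction, which is exactly the information flow the
association matrix encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .design import ModelDesign
from .sampler import PosteriorSampleSet, _as_rng, _sample_mvn_batch, _trunc_normal

__all__ = [
    "PredictionSet",
    "Scenario",
    "linear_predictor",
    "predict_marginal",
    "predict_conditional",
    "scenario_predict",
    "expected_richness",
]


def linear_predictor(
    beta: np.ndarray, Lambda: np.ndarray, X_new: np.ndarray, H_new: np.ndarray
) -> np.ndarray:
    """L = X B + H Lambda for one parameter draw."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    H_new = np.atleast_2d(np.asarray(H_new, dtype=float))
    if X_new.shape[1] != beta.shape[0]:
        raise ValueError("X_new width does not match beta")
    if H_new.shape[1] != Lambda.shape[0]:
        raise ValueError("H_new width does not match Lambda")
    return X_new @ beta + H_new @ Lambda


@dataclass
class PredictionSet:
    """Per-draw and posterior-mean predictions over sites × column-units.

    ``linear`` is on the model (probit / centred-log) scale; ``response``
    maps occurrence columns through the probit CDF (probabilities) and
    log-normal columns back to their natural scale.
    """

    linear: np.ndarray | None      # (n_draws, n_sites, n_cols) or None
    response: np.ndarray | None
    mean_linear: np.ndarray
    mean_response: np.ndarray
    labels: list[str]
    site_ids: list
    probit_cols: np.ndarray
    target_cols: np.ndarray = field(default=None)

    @property
    def n_draws(self) -> int:
        return 0 if self.linear is None else self.linear.shape[0]

    def occurrence_probabilities(self, design: ModelDesign) -> pd.DataFrame:
        occ = [r for r in design.Y.rtypes if r.role == "occurrence"]
        if not occ:
            raise ValueError("model has no occurrence response type")
        blk = design.Y.block_slice(occ[0].name)
        return pd.DataFrame(
            self.mean_response[:, blk], index=self.site_ids, columns=design.Y.species
        )


def _to_response(
    L: np.ndarray,
    sigma2: np.ndarray,
    design: ModelDesign,
    backtransform: str,
) -> np.ndarray:
    """Map model-scale linear predictors to probabilities / natural scales."""
    is_probit = design.Y.is_probit
    out = np.empty_like(L)
    out[..., is_probit] = special.ndtr(L[..., is_probit])
    ln = ~is_probit
    center = design.Y.col_center[ln]
    scale = design.Y.col_scale[ln]
    log_val = center + scale * L[..., ln]
    if backtransform == "mean":
        sig = np.asarray(sigma2, dtype=float)[..., ln]
        if sig.ndim == log_val.ndim - 1:      # insert the site axis
            sig = sig[..., None, :]
        log_val = log_val + 0.5 * (scale**2) * sig
    elif backtransform != "median":
        raise ValueError("backtransform must be 'median' or 'mean'")
    out[..., ln] = np.exp(log_val)
    return out


def _resolve_X(design: ModelDesign, X_new) -> tuple[np.ndarray, list]:
    if X_new is None:
        return design.env.X, list(design.env.site_ids)
    if isinstance(X_new, pd.DataFrame):
        return design.env.transform(X_new), list(X_new.index)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != design.env.X.shape[1]:
        raise ValueError("X_new must already carry the intercept column")
    return X_new, list(range(len(X_new)))


def _draw_indices(samples: PosteriorSampleSet, n_draws: int | None) -> np.ndarray:
    total = samples.n_total
    if n_draws is None or n_draws >= total:
        return np.arange(total)
    return np.unique(np.linspace(0, total - 1, n_draws).astype(int))


def predict_marginal(
    samples: PosteriorSampleSet,
    design: ModelDesign,
    X_new=None,
    seed=None,
    n_draws: int | None = None,
    backtransform: str = "median",
    keep_draws: bool = True,
) -> PredictionSet:
    """Predict new sites marginally over the latent factors.

    Per retained draw a fresh factor-score row is sampled from its standard
    normal prior for every new site, so predictions integrate over the
    residual association structure.
    """
    rng = _as_rng(seed)
    X, site_ids = _resolve_X(design, X_new)
    idx = _draw_indices(samples, n_draws)
    beta = samples.stacked("beta")[idx]
    Lam = samples.stacked("Lambda")[idx]
    sig2 = samples.stacked("sigma2")[idx]
    n_new = X.shape[0]
    nf = Lam.shape[1]

    H_new = rng.standard_normal((len(idx), n_new, nf))
    L = np.einsum("ik,dkc->dic", X, beta) + np.einsum("dif,dfc->dic", H_new, Lam)
    resp = _to_response(L, sig2, design, backtransform)
    return PredictionSet(
        linear=L if keep_draws else None,
        response=resp if keep_draws else None,
        mean_linear=L.mean(axis=0),
        mean_response=resp.mean(axis=0),
        labels=design.Y.column_labels,
        site_ids=site_ids,
        probit_cols=design.Y.is_probit,
        target_cols=np.arange(design.Y.n_cols),
    )


def _parse_conditions(
    design: ModelDesign, conditions: Mapping, n_new: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize a conditioning spec to (columns, model-scale values, mask).

    Keys are (species, rtype_name) pairs or "species/rtype" strings; values
    are scalars or per-site arrays on the natural scale (occurrence in
    {0, 1}); NaN leaves that site unconditioned for that column.
    """
    cols, vals = [], []
    for key, value in conditions.items():
        if isinstance(key, str):
            species, rname = key.rsplit("/", 1)
        else:
            species, rname = key
        try:
            c = design.Y.col_index(species, rname)
        except ValueError as exc:
            raise ValueError(f"unknown conditioning column {species}/{rname}") from exc
        v = np.broadcast_to(np.asarray(value, dtype=float), (n_new,)).copy()
        obs = np.isfinite(v)
        if design.Y.is_probit[c]:
            if obs.any() and not np.all(np.isin(v[obs], (0.0, 1.0))):
                raise ValueError(f"occurrence conditioning values must be 0/1 ({species}/{rname})")
        else:
            if np.any(v[obs] <= 0):
                raise ValueError(f"log-normal conditioning values must be positive ({species}/{rname})")
            v[obs] = (np.log(v[obs]) - design.Y.col_center[c]) / design.Y.col_scale[c]
        cols.append(c)
        vals.append(v)
    cols = np.asarray(cols, dtype=int)
    values = np.array(vals).T  # n_new x n_cond
    mask = np.isfinite(values)
    values = np.where(mask, values, 0.0)
    return cols, values, mask


def predict_conditional(
    samples: PosteriorSampleSet,
    design: ModelDesign,
    X_new=None,
    conditions: Mapping | None = None,
    n_inner: int = 50,
    n_discard: int = 20,
    seed=None,
    n_draws: int | None = None,
    backtransform: str = "median",
    keep_draws: bool = True,
) -> PredictionSet:
    """Predict unconditioned columns given fixed values on conditioned ones.

    For each posterior draw, an inner Gibbs run alternates the new sites'
    factor scores with the probit augmentation of conditioned occurrence
    cells; the final scores generate the prediction.  Conditioned cells with
    NaN values are treated as unconditioned site-by-site.
    """
    if not conditions:
        raise ValueError("conditions must be nonempty; use predict_marginal otherwise")
    rng = _as_rng(seed)
    X, site_ids = _resolve_X(design, X_new)
    n_new = X.shape[0]
    cols, cvals, cmask = _parse_conditions(design, conditions, n_new)
    if len(set(cols.tolist())) == design.Y.n_cols:
        raise ValueError("conditioning on every column leaves nothing to predict")
    target = np.setdiff1d(np.arange(design.Y.n_cols), cols)

    idx = _draw_indices(samples, n_draws)
    beta = samples.stacked("beta")[idx]
    Lam = samples.stacked("Lambda")[idx]
    sig2 = samples.stacked("sigma2")[idx]
    nf = Lam.shape[1]
    nd = len(idx)
    probit_c = design.Y.is_probit[cols]

    L_out = np.empty((nd, n_new, design.Y.n_cols))
    eye = np.eye(nf)
    for d in range(nd):
        B, Lm, s2 = beta[d], Lam[d], sig2[d]
        Lfix = X @ B
        if nf == 0:
            L_out[d] = Lfix
            continue
        Lc = Lm[:, cols]                    # nf x n_cond
        s2c = s2[cols]
        w = np.where(probit_c[None, :], (2.0 * cvals - 1.0) * 0.8, cvals)
        eta = rng.standard_normal((n_new, nf))
        for _ in range(n_discard + n_inner):
            loc = Lfix[:, cols] + eta @ Lc
            if probit_c.any():
                pa = probit_c
                w[:, pa] = _trunc_normal(loc[:, pa], cvals[:, pa] > 0.5, rng)
            ytil = np.where(probit_c[None, :], w, cvals)
            Wgt = cmask / s2c[None, :]
            prec = eye[None] + np.einsum("kc,ic,lc->ikl", Lc, Wgt, Lc)
            rhs = np.einsum("kc,ic->ik", Lc, Wgt * (ytil - Lfix[:, cols]))
            _, eta = _sample_mvn_batch(prec, rhs, rng)
        L_out[d] = Lfix + eta @ Lm
    resp = _to_response(L_out, sig2, design, backtransform)
    return PredictionSet(
        linear=L_out if keep_draws else None,
        response=resp if keep_draws else None,
        mean_linear=L_out.mean(axis=0),
        mean_response=resp.mean(axis=0),
        labels=design.Y.column_labels,
        site_ids=site_ids,
        probit_cols=design.Y.is_probit,
        target_cols=target,
    )


@dataclass
class Scenario:
    """A conditioning specification for scenario simulation.

    ``covariates`` maps covariate names to fixed values on the original
    scale, or the strings ``"low"``/``"high"`` (dataset quantiles);
    ``condition`` fixes focal-species column values ((species, rtype) keys,
    natural scale, occurrence in {0, 1}); unset entries are marginalized.
    ``focal_species`` is excluded from community summaries.
    """

    covariates: dict = field(default_factory=dict)
    condition: dict = field(default_factory=dict)
    focal_species: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        for key in self.condition:
            species, rname = (key.rsplit("/", 1) if isinstance(key, str) else key)
            if self.focal_species is None:
                self.focal_species = species


@dataclass
class ScenarioResult:
    prediction: PredictionSet
    occurrence: pd.DataFrame          # non-focal occurrence probabilities (posterior mean)
    richness_per_draw: np.ndarray     # (n_draws, n_sites)
    richness_mean: float
    richness_interval: tuple[float, float]


def expected_richness(occurrence_probabilities: np.ndarray, interval: float = 0.95) -> dict:
    """Richness as the per-draw sum of species occurrence probabilities.

    Accepts (n_draws, ..., n_species) arrays; the species axis is last.
    """
    p = np.asarray(occurrence_probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    per_draw = p.sum(axis=-1)
    alpha = (1.0 - interval) / 2.0
    return {
        "per_draw": per_draw,
        "mean": per_draw.mean(axis=0),
        "lower": np.quantile(per_draw, alpha, axis=0),
        "upper": np.quantile(per_draw, 1.0 - alpha, axis=0),
    }


def scenario_predict(
    samples: PosteriorSampleSet,
    design: ModelDesign,
    scenario: Scenario,
    reference_covariates: pd.DataFrame | None = None,
    seed=None,
    n_draws: int | None = None,
    quantiles: tuple[float, float] = (0.1, 0.9),
    n_inner: int = 50,
    n_discard: int = 20,
) -> ScenarioResult:
    """Predict non-focal species occurrences and richness under a scenario.

    Reference sites supply the covariate values that the scenario does not
    fix; ``"low"``/``"high"`` map to the reference quantiles.
    """
    if reference_covariates is None:
        reference_covariates = pd.DataFrame(
            design.env.original_scale(),
            index=design.env.site_ids,
            columns=design.env.covariate_names,
        )
    cov = reference_covariates.copy()
    for name, value in scenario.covariates.items():
        if name not in cov.columns:
            raise ValueError(f"scenario references unknown covariate {name!r}")
        if isinstance(value, str):
            if value not in ("low", "high"):
                raise ValueError(f"covariate setting must be numeric or 'low'/'high', got {value!r}")
            q = quantiles[0] if value == "low" else quantiles[1]
            value = float(reference_covariates[name].quantile(q))
        cov[name] = float(value)

    focal = scenario.focal_species
    if focal is not None and focal not in design.Y.species:
        raise ValueError(f"scenario references unknown species {focal!r}")

    if scenario.condition:
        pred = predict_conditional(
            samples, design, cov, scenario.condition,
            n_inner=n_inner, n_discard=n_discard, seed=seed, n_draws=n_draws,
        )
    else:
        pred = predict_marginal(samples, design, cov, seed=seed, n_draws=n_draws)

    occ_rt = [r for r in design.Y.rtypes if r.role == "occurrence"]
    if not occ_rt:
        raise ValueError("scenario richness requires an occurrence response type")
    blk = design.Y.block_slice(occ_rt[0].name)
    species = design.Y.species
    keep = [s != focal for s in species]
    probs = pred.response[:, :, blk][:, :, keep]
    rich = expected_richness(probs)
    occurrence = pd.DataFrame(
        probs.mean(axis=0), index=pred.site_ids, columns=[s for s in species if s != focal]
    )
    overall = rich["per_draw"].mean(axis=1)  # mean over reference sites per draw
    return ScenarioResult(
        prediction=pred,
        occurrence=occurrence,
        richness_per_draw=rich["per_draw"],
        richness_mean=float(overall.mean()),
        richness_interval=(float(np.quantile(overall, 0.025)), float(np.quantile(overall, 0.975))),
    )
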