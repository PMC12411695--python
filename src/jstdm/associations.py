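"""Association matrices among column-units and their posterior summaries.

The latent loadings induce a covariance among column-units,

    Omega[a, b] = sum_f Lambda[f, a] Lambda[f, b],

interpreted per entry: e.g. a positive association between the abundance
column of species 1 and a trait column of species 2 means species 2 carries
especially large trait values at sites where species 1 is abundant, beyond
what the measured covariates explain.  Under the intercept-only null model
Omega captures the raw associations; under the environmental model the
residual ones, and comparing the two shows which associations environmental
variation explains away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelDesign
from .sampler import PosteriorSampleSet

__all__ = [
    "omega_from_lambda",
    "AssociationMatrix",
    "association_matrix",
    "association_support",
    "compare_associations",
    "factor_importance",
    "variance_partitioning",
]


def omega_from_lambda(Lambda: np.ndarray) -> np.ndarray:
    """One association-matrix draw from one loadings draw: Omega = Lambda' Lambda."""
    Lambda = np.asarray(Lambda, dtype=float)
    return Lambda.T @ Lambda


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    """Correlation scaling of one covariance draw; zero-variance entries -> NaN."""
    d = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    return np.clip(corr, -1.0, 1.0, out=corr, where=np.isfinite(corr))


@dataclass
class AssociationMatrix:
    """Posterior summary of the column-unit association matrix.

    ``frac_pos``/``frac_neg`` are fractions of posterior draws with a strictly
    positive / strictly negative entry (exact zeros count in neither), used
    for the posterior-support calls.
    """

    mean_cov: np.ndarray
    mean_corr: np.ndarray
    frac_pos: np.ndarray
    frac_neg: np.ndarray
    n_draws: int
    labels: list[str]
    draws: np.ndarray | None = None  # (n_draws, p, p) covariance draws, optional

    @property
    def n_cols(self) -> int:
        return self.mean_cov.shape[0]

    def support(self, level: float = 0.90) -> np.ndarray:
        """Signed support map: +1 / -1 where the posterior probability of the
        entry being positive / negative reaches ``level``, 0 otherwise and NaN
        where the entry is degenerate (every draw exactly zero)."""
        if not (0.5 < level <= 1.0):
            raise ValueError("support level must lie in (0.5, 1]")
        if self.n_draws < 100:
            warnings.warn(
                f"support computed from only {self.n_draws} draws; "
                "calls below 100 draws are unreliable",
                stacklevel=2,
            )
        out = np.zeros_like(self.frac_pos)
        out[self.frac_pos >= level] = 1.0
        out[self.frac_neg >= level] = -1.0
        degenerate = (self.frac_pos == 0.0) & (self.frac_neg == 0.0)
        out[degenerate] = np.nan
        return out

    def to_frame(self, scale: str = "correlation") -> pd.DataFrame:
        mat = self.mean_corr if scale == "correlation" else self.mean_cov
        return pd.DataFrame(mat, index=self.labels, columns=self.labels)


def association_matrix(
    samples: PosteriorSampleSet,
    labels: list[str] | None = None,
    keep_draws: bool | None = None,
) -> AssociationMatrix:
    """Posterior association summary, streamed over draws.

    The correlation scale is computed per draw and then averaged, so each
    summand is a valid correlation matrix.  ``keep_draws`` defaults to True
    for small models (p <= 80) and False otherwise.
    """
    Lam = samples.stacked("Lambda")
    n_draws, _, p = Lam.shape
    if keep_draws is None:
        keep_draws = p <= 80
    if labels is None:
        labels = [f"col{c}" for c in range(p)]

    sum_cov = np.zeros((p, p))
    sum_corr = np.zeros((p, p))
    n_corr = np.zeros((p, p))
    n_pos = np.zeros((p, p))
    n_neg = np.zeros((p, p))
    draws = np.empty((n_draws, p, p)) if keep_draws else None
    for d in range(n_draws):
        omega = omega_from_lambda(Lam[d])
        sum_cov += omega
        corr = _corr_from_cov(omega)
        finite = np.isfinite(corr)
        sum_corr[finite] += corr[finite]
        n_corr += finite
        n_pos += omega > 0
        n_neg += omega < 0
        if keep_draws:
            draws[d] = omega
    with np.errstate(invalid="ignore"):
        mean_corr = np.where(n_corr > 0, sum_corr / np.maximum(n_corr, 1), np.nan)
    return AssociationMatrix(
        mean_cov=sum_cov / n_draws,
        mean_corr=mean_corr,
        frac_pos=n_pos / n_draws,
        frac_neg=n_neg / n_draws,
        n_draws=n_draws,
        labels=list(labels),
        draws=draws,
    )


def association_support(draws: np.ndarray, level: float = 0.90) -> np.ndarray:
    """Signed support map straight from an array of association draws."""
    draws = np.asarray(draws, dtype=float)
    n = draws.shape[0]
    am = AssociationMatrix(
        mean_cov=draws.mean(axis=0),
        mean_corr=np.full(draws.shape[1:], np.nan),
        frac_pos=np.mean(draws > 0, axis=0),
        frac_neg=np.mean(draws < 0, axis=0),
        n_draws=n,
        labels=[f"col{c}" for c in range(draws.shape[1])],
    )
    return am.support(level)


def compare_associations(
    assoc_null: AssociationMatrix,
    assoc_env: AssociationMatrix,
    level: float = 0.90,
    block_labels: list[str] | None = None,
) -> dict:
    """Classify entries between the null and environmental model.

    retained: flagged (same sign) in both; explained-away: flagged in the
    null model only; emergent: flagged in the environmental model only.
    Returns the per-entry classification plus counts, optionally aggregated
    per response-type block (``block_labels`` gives each column's block).
    """
    if assoc_null.labels != assoc_env.labels:
        raise ValueError("association matrices cover different column-units")
    s0 = assoc_null.support(level)
    s1 = assoc_env.support(level)
    f0 = np.nan_to_num(s0) != 0
    f1 = np.nan_to_num(s1) != 0
    cls = np.full(s0.shape, "none", dtype=object)
    cls[f0 & f1] = "retained"
    cls[f0 & f1 & (np.nan_to_num(s0) != np.nan_to_num(s1))] = "sign_change"
    cls[f0 & ~f1] = "explained_away"
    cls[~f0 & f1] = "emergent"
    iu = np.triu_indices(s0.shape[0], k=1)
    upper = cls[iu]
    counts = {
        k: int(np.sum(upper == k))
        for k in ("retained", "explained_away", "emergent", "sign_change")
    }
    result = {"classification": cls, "counts": counts, "level": level}
    if block_labels is not None:
        blocks = np.asarray(block_labels)
        recs = []
        for b1 in np.unique(blocks):
            for b2 in np.unique(blocks):
                sel = np.ix_(blocks == b1, blocks == b2)
                sub = cls[sel]
                recs.append(
                    {
                        "block_row": b1,
                        "block_col": b2,
                        **{k: int(np.sum(sub == k)) for k in ("retained", "explained_away", "emergent")},
                    }
                )
        result["per_block"] = pd.DataFrame(recs)
    return result


def factor_importance(samples: PosteriorSampleSet) -> pd.DataFrame:
    """Posterior mean share of the association-matrix trace per latent factor."""
    Lam = samples.stacked("Lambda")  # (draws, n_f, p)
    ss = np.sum(Lam**2, axis=2)      # (draws, n_f)
    tot = ss.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("all-zero loadings in at least one draw")
    shares = (ss / tot).mean(axis=0)
    order = np.argsort(shares)[::-1]
    return pd.DataFrame(
        {"factor": order, "share": shares[order]},
    ).reset_index(drop=True)


def variance_partitioning(
    samples: PosteriorSampleSet,
    design: ModelDesign,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Split each column-unit's predictor variance into covariate groups,
    latent factors and residual.

    Uses the realized design (empirical covariance of the fitted X): the
    contribution of group g is sum_{k in g} beta_k (S beta)_k with S the
    covariate covariance, the factor part is sum_f lambda_f^2 and the
    residual part sigma2 (log-normal) or 1 (probit); proportions are
    normalized per draw and averaged over draws.
    """
    X = design.env.X
    names = ["intercept"] + list(design.env.covariate_names)
    if groups is None:
        groups = {n: [n] for n in design.env.covariate_names}
    idx = {n: k for k, n in enumerate(names)}
    S = np.cov(X, rowvar=False, ddof=0).reshape(len(names), len(names))

    beta = samples.stacked("beta")     # (draws, n_c, p)
    Lam = samples.stacked("Lambda")
    sig2 = samples.stacked("sigma2")
    n_draws, _, p = beta.shape
    is_probit = design.Y.is_probit

    Sb = np.einsum("kl,dlc->dkc", S, beta)
    env_parts = {}
    for gname, members in groups.items():
        ks = [idx[m] for m in members]
        env_parts[gname] = np.sum(beta[:, ks, :] * Sb[:, ks, :], axis=1)
    fac = np.sum(Lam**2, axis=1)
    resid = np.where(is_probit[None, :], 1.0, sig2)
    total = sum(env_parts.values()) + fac + resid
    rows = {g: (v / total).mean(axis=0) for g, v in env_parts.items()}
    rows["latent_factors"] = (fac / total).mean(axis=0)
    rows["residual"] = (resid / total).mean(axis=0)
    out = pd.DataFrame(rows, index=design.Y.column_labels)
    out.insert(0, "species", [cu.species for cu in design.Y.column_units])
    out.insert(1, "rtype", [cu.rtype.name for cu in design.Y.column_units])
    return out
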