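"""K-fold baseline and conditional cross-validation over sites.

Baseline CV masks the entire response vector of the test-fold sites and
predicts marginally from the environmental covariates alone.  Conditional CV
masks only the trait columns, conditions on the test sites' observed
occurrence and conditional-abundance columns, and predicts the trait
columns — so any shared latent structure between abundances and traits is
exploited.  Predictive performance is the Pearson correlation between
predicted and observed values per species-trait combination, computed on the
log (model) scale and kept signed: a negative correlation means predictions
worse than random, and squaring would hide that.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import build_design
from .priors import PriorConfig
from .prediction import predict_conditional, predict_marginal
from .responses import ResponseType
from .sampler import run_mcmc

__all__ = [
    "make_folds",
    "cross_validate",
    "predictive_correlation",
    "improvement_summary",
]

logger = logging.getLogger(__name__)


def make_folds(site_ids: Sequence, k: int, seed=None) -> np.ndarray:
    """Partition sites into k folds of near-equal size (sizes differ by <= 1)."""
    n = len(site_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k cannot exceed the number of sites")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = np.arange(n) % k
    return labels


def cross_validate(
    abundance: pd.DataFrame,
    trait_tables: Mapping[str, pd.DataFrame],
    covariates: pd.DataFrame | None,
    rtypes: Sequence[ResponseType] | None = None,
    folds: np.ndarray | None = None,
    k: int = 10,
    mode: str = "both",
    priors: PriorConfig | None = None,
    chains: int = 4,
    iterations: int = 4000,
    burn_in: int | None = None,
    thin: int = 10,
    n_inner: int = 50,
    n_discard: int = 20,
    n_pred_draws: int | None = 200,
    seed: int | None = 0,
    scale_responses: bool = True,
    scale_covariates: bool = True,
    min_prevalence: int = 0,
) -> pd.DataFrame:
    """Refit per fold and predict held-out trait cells.

    Returns a tidy table with one row per observed held-out trait cell:
    fold, site, species, trait, the observed log value and the predicted log
    value(s) for the requested mode(s).  Species that a fold leaves with
    zero presences (or no observed trait values) in training are skipped for
    that fold with a warning.  MCMC settings are recorded in ``df.attrs``.
    """
    if mode not in ("baseline", "conditional", "both"):
        raise ValueError("mode must be 'baseline', 'conditional' or 'both'")
    if burn_in is None:
        burn_in = iterations // 4
    site_ids = list(abundance.index)
    if folds is None:
        folds = make_folds(site_ids, k, seed)
    folds = np.asarray(folds)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(np.unique(folds)) * 3)]

    trait_names = [r.name for r in rtypes if r.role == "trait"] if rtypes else list(trait_tables)
    records = []
    for f in np.unique(folds):
        train = [s for s, lab in zip(site_ids, folds) if lab != f]
        test = [s for s, lab in zip(site_ids, folds) if lab == f]
        ab_tr = abundance.loc[train]
        present_tr = ab_tr > 0
        usable = []
        for sp in abundance.columns:
            if present_tr[sp].sum() == 0:
                warnings.warn(f"fold {f}: species {sp!r} has no training presences; skipped")
                continue
            if any(
                not np.isfinite(trait_tables[t].loc[train, sp]).any() for t in trait_names
            ):
                warnings.warn(f"fold {f}: species {sp!r} has no training trait values; skipped")
                continue
            usable.append(sp)
        if not usable:
            warnings.warn(f"fold {f}: no usable species; fold skipped")
            continue

        design = build_design(
            ab_tr[usable],
            {t: trait_tables[t].loc[train, usable] for t in trait_names},
            covariates.loc[train] if covariates is not None else None,
            rtypes=rtypes,
            scale_responses=scale_responses,
            scale_covariates=scale_covariates,
            min_prevalence=min_prevalence,
            on_trait_without_presence="mask",
        )
        samples = run_mcmc(
            design, priors, chains=chains, iterations=iterations,
            burn_in=burn_in, thin=thin, seed=fold_seeds[3 * int(f)], record_h=False,
        )

        X_test = covariates.loc[test] if covariates is not None else np.ones((len(test), 1))
        preds = {}
        if mode in ("baseline", "both"):
            preds["baseline"] = predict_marginal(
                samples, design, X_test, seed=fold_seeds[3 * int(f) + 1],
                n_draws=n_pred_draws, keep_draws=False,
            ).mean_linear
        if mode in ("conditional", "both"):
            conditions = {}
            ab_te = abundance.loc[test, usable]
            occ = [r for r in design.Y.rtypes if r.role == "occurrence"]
            abu = [r for r in design.Y.rtypes if r.role == "abundance"]
            for sp in usable:
                if occ:
                    conditions[(sp, occ[0].name)] = (ab_te[sp] > 0).astype(float).to_numpy()
                if abu:
                    vals = ab_te[sp].to_numpy(dtype=float)
                    conditions[(sp, abu[0].name)] = np.where(vals > 0, vals, np.nan)
            preds["conditional"] = predict_conditional(
                samples, design, X_test, conditions,
                n_inner=n_inner, n_discard=n_discard,
                seed=fold_seeds[3 * int(f) + 2], n_draws=n_pred_draws, keep_draws=False,
            ).mean_linear

        for t in trait_names:
            blk = design.Y.block_slice(t)
            center = design.Y.col_center[blk]
            scale = design.Y.col_scale[blk]
            obs_tab = trait_tables[t].loc[test, usable]
            ab_mask = abundance.loc[test, usable] > 0
            for si, site in enumerate(test):
                for ji, sp in enumerate(usable):
                    v = obs_tab.iloc[si, ji]
                    if not (np.isfinite(v) and v > 0 and ab_mask.iloc[si, ji]):
                        continue
                    rec = {
                        "fold": int(f), "site": site, "species": sp, "trait": t,
                        "observed_log": float(np.log(v)),
                    }
                    for m, arr in preds.items():
                        rec[f"pred_{m}"] = float(center[ji] + scale[ji] * arr[si, blk][ji])
                    records.append(rec)

    out = pd.DataFrame.from_records(records)
    out.attrs["mcmc"] = {
        "chains": chains, "iterations": iterations, "burn_in": burn_in,
        "thin": thin, "seed": seed, "n_inner": n_inner, "n_discard": n_discard,
    }
    return out


def predictive_correlation(
    table: pd.DataFrame,
    pred_col: str,
    obs_col: str = "observed_log",
    by: tuple[str, str] = ("species", "trait"),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Signed Pearson correlation per species-trait combination (log scale).

    Combinations with fewer than ``min_pairs`` observations or zero variance
    on either side are undefined and reported as NaN, never as 0.
    """
    rows = []
    for keys, grp in table.groupby(list(by)):
        x = grp[pred_col].to_numpy(dtype=float)
        y = grp[obs_col].to_numpy(dtype=float)
        if len(x) < min_pairs or np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append(dict(zip(by, keys)) | {"correlation": r, "n": len(x)})
    return pd.DataFrame(rows)


def improvement_summary(
    corr_baseline: pd.DataFrame,
    corr_conditional: pd.DataFrame,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-trait shares of species improved/worsened by conditioning.

    ``share_improved`` counts conditional > baseline; the thresholded shares
    count absolute differences of at least ``threshold`` in either direction;
    the three thresholded categories (improved, worsened, within) partition
    the species.
    """
    merged = corr_baseline.merge(
        corr_conditional, on=["species", "trait"], suffixes=("_baseline", "_conditional")
    ).dropna(subset=["correlation_baseline", "correlation_conditional"])
    rows = []
    for trait, grp in merged.groupby("trait"):
        diff = grp["correlation_conditional"] - grp["correlation_baseline"]
        n = len(grp)
        rows.append({
            "trait": trait,
            "n_species": n,
            "share_improved": float((diff > 0).mean()),
            "share_improved_ge_threshold": float((diff >= threshold).mean()),
            "share_worsened_ge_threshold": float((diff <= -threshold).mean()),
            "share_within_threshold": float((diff.abs() < threshold).mean()),
        })
    return pd.DataFrame(rows)
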