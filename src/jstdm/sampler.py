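"""Blocked Gibbs sampler for the joint species-trait distribution model.

Model
-----
Each column-unit c = (species j, response type z) has linear predictor

    L[i, c] = sum_k X[i, k] B[k, c] + sum_f H[i, f] Lambda[f, c]

Occurrence columns observe y = 1{w > 0} with w ~ N(L, 1) (probit link,
truncated-normal data augmentation); log-normal columns observe the (scaled)
log response with residual variance sigma2[c].  The environmental responses
are tied across column-units through species-level traits:

    B[:, c] ~ N(Gamma @ ttilde_c, V)

where ttilde_c is the response-type-expanded trait row of the column's
species, Gamma holds the per-type trait effects and V the covariance of the
species-specific deviations.  Latent factor loadings carry a multiplicative
gamma process shrinkage prior; factor scores are a-priori standard normal.
Unobserved cells (traits and conditional abundance where the species is
absent, or cells masked for cross-validation) are skipped in every
likelihood sum — they are marginalized, never imputed.

All full conditionals are conjugate, so one sweep is: probit latents ->
(Gamma, V, B) -> (H, Lambda, shrinkage) -> sigma2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from .design import ModelDesign
from .priors import PriorConfig

__all__ = [
    "PosteriorState",
    "PosteriorSampleSet",
    "SamplerWorkspace",
    "init_state",
    "update_probit_latent",
    "update_beta_gamma",
    "update_factors",
    "update_sigma",
    "beta_conditional_moments",
    "run_mcmc",
    "convergence_diagnostics",
]

logger = logging.getLogger(__name__)

_TRUNC_EPS = 1e-14
_HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))  # E[w | w>0, w~N(0,1)]


# ---------------------------------------------------------------------------
# workspace and state containers
# ---------------------------------------------------------------------------
@dataclass
class SamplerWorkspace:
    """Immutable precomputed quantities shared by every sweep."""

    X: np.ndarray            # n_sites x n_c
    Yf: np.ndarray           # responses with unobserved cells zero-filled
    M: np.ndarray            # float {0,1} observation mask
    is_probit: np.ndarray    # per-column bool
    Ttilde: np.ndarray       # n_cols x q expanded trait design
    XtX_obs: np.ndarray      # n_cols x n_c x n_c, X_o' X_o per column
    n_obs: np.ndarray        # observed cells per column
    TtT: np.ndarray          # q x q

    @classmethod
    def from_design(cls, design: ModelDesign) -> "SamplerWorkspace":
        X = design.env.X
        M = design.Y.observed.astype(float)
        Yf = np.where(design.Y.observed, design.Y.values, 0.0)
        XtX_obs = np.einsum("ic,ik,il->ckl", M, X, X)
        return cls(
            X=X,
            Yf=Yf,
            M=M,
            is_probit=design.Y.is_probit,
            Ttilde=design.Ttilde.values,
            XtX_obs=XtX_obs,
            n_obs=M.sum(axis=0),
            TtT=design.Ttilde.values.T @ design.Ttilde.values,
        )

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def n_c(self) -> int:
        return self.X.shape[1]

    @property
    def n_cols(self) -> int:
        return self.Yf.shape[1]


@dataclass
class PosteriorState:
    """One MCMC state of every model block."""

    beta: np.ndarray      # n_c x n_cols
    gamma: np.ndarray     # n_c x q
    V: np.ndarray         # n_c x n_c
    H: np.ndarray         # n_sites x n_f
    Lambda: np.ndarray    # n_f x n_cols
    sigma2: np.ndarray    # n_cols (1.0 on probit columns)
    psi: np.ndarray       # n_f x n_cols local shrinkage precisions
    delta: np.ndarray     # n_f column-shrinkage multipliers
    z: np.ndarray         # n_sites x n_cols probit augmentation values

    def copy(self) -> "PosteriorState":
        return PosteriorState(*(np.array(getattr(self, f), copy=True) for f in (
            "beta", "gamma", "V", "H", "Lambda", "sigma2", "psi", "delta", "z")))

    @property
    def tau(self) -> np.ndarray:
        """Cumulative column shrinkage precisions (product of multipliers)."""
        return np.cumprod(self.delta)


@dataclass
class PosteriorSampleSet:
    """Thinned posterior snapshots stacked as (chain, draw, ...) arrays."""

    beta: np.ndarray
    gamma: np.ndarray
    V: np.ndarray
    Lambda: np.ndarray
    sigma2: np.ndarray
    H: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.beta.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    @property
    def n_factors(self) -> int:
        return self.Lambda.shape[2]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} was not recorded")
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_mvn_batch(prec: np.ndarray, rhs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw x_b ~ N(prec_b^{-1} rhs_b, prec_b^{-1}) for a batch of precisions.

    Raises LinAlgError if any precision matrix is not positive definite —
    degeneracy is surfaced, never silently regularized.
    """
    L = np.linalg.cholesky(prec)          # batch lower Cholesky
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    u = rng.standard_normal(rhs.shape)
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), u[..., None])[..., 0]
    return mean, mean + noise


def _trunc_normal(loc: np.ndarray, positive: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance normal at ``loc`` truncated to (0, inf) or (-inf, 0]."""
    u = rng.uniform(size=loc.shape)
    p_neg = special.ndtr(-loc)  # P(w <= 0)
    prob = np.where(positive, p_neg + u * (1.0 - p_neg), u * p_neg)
    w = loc + special.ndtri(np.clip(prob, _TRUNC_EPS, 1.0 - _TRUNC_EPS))
    # clamp to the truncation region (guards the extreme-|loc| tail where the
    # inverse-CDF saturates); keeps the sign invariant exact
    return np.where(positive, np.maximum(w, 1e-12), np.minimum(w, 0.0))


def _inv_wishart(df: float, S: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from the inverse-Wishart via Bartlett decomposition."""
    p = S.shape[0]
    cS = np.linalg.cholesky(S)  # raises if S not PD
    A = np.zeros((p, p))
    idx = np.tril_indices(p, k=-1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    # W = C^{-T} A A' C^{-1} ~ Wishart(df, S^{-1});  V = W^{-1} ~ IW(df, S)
    from scipy.linalg import solve_triangular

    CA = solve_triangular(cS, A, lower=True, trans="T")
    W = CA @ CA.T
    return np.linalg.inv(W)


def _ystar(state: PosteriorState, ws: SamplerWorkspace) -> np.ndarray:
    """Working responses: probit columns replaced by their latent values."""
    return np.where(ws.is_probit[None, :], state.z, ws.Yf)


def _ws(design) -> SamplerWorkspace:
    return design if isinstance(design, SamplerWorkspace) else SamplerWorkspace.from_design(design)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------
def init_state(design: ModelDesign | SamplerWorkspace, priors: PriorConfig, seed) -> PosteriorState:
    """Deterministic-under-seed starting state.

    B comes from a ridge-stabilized per-column regression of the (augmented)
    observed responses on X; factor scores and loadings start as
    small-variance draws; residual variances from the ridge residuals.
    """
    ws = _ws(design)
    rng = _as_rng(seed)
    n, n_c, n_cols = ws.n_sites, ws.n_c, ws.n_cols
    if np.linalg.matrix_rank(ws.X) < n_c:
        raise ValueError("environmental design X is rank deficient")

    # probit latents at the mean of the standard truncated normal
    z = np.where(
        ws.is_probit[None, :] & (ws.M > 0),
        (2.0 * ws.Yf - 1.0) * _HALF_NORMAL_MEAN,
        0.0,
    )
    ystar = np.where(ws.is_probit[None, :], z, ws.Yf)

    ridge = 1e-3
    prec = ws.XtX_obs + ridge * np.eye(n_c)[None]
    rhs = np.einsum("ik,ic->ck", ws.X, ws.M * ystar)
    beta = np.linalg.solve(prec, rhs[..., None])[..., 0].T  # n_c x n_cols

    resid = (ystar - ws.X @ beta) * ws.M
    denom = np.maximum(ws.n_obs, 1.0)
    sigma2 = np.maximum(np.sum(resid**2, axis=0) / denom, 1e-3)
    sigma2[ws.is_probit] = 1.0

    n_f = priors.n_factors
    q = ws.Ttilde.shape[1]
    return PosteriorState(
        beta=beta,
        gamma=np.zeros((n_c, q)),
        V=np.eye(n_c),
        H=0.1 * rng.standard_normal((n, n_f)),
        Lambda=0.1 * rng.standard_normal((n_f, n_cols)),
        sigma2=sigma2,
        psi=np.ones((n_f, n_cols)),
        delta=np.ones(n_f),
        z=z,
    )


# ---------------------------------------------------------------------------
# conditional updates
# ---------------------------------------------------------------------------
def update_probit_latent(state: PosteriorState, design, rng) -> PosteriorState:
    """Truncated-normal augmentation draw for every observed occurrence cell."""
    ws = _ws(design)
    rng = _as_rng(rng)
    cols = np.flatnonzero(ws.is_probit)
    if cols.size == 0:
        return state
    L = ws.X @ state.beta[:, cols] + state.H @ state.Lambda[:, cols]
    y = ws.Yf[:, cols]
    w = _trunc_normal(L, y > 0.5, rng)
    obs = ws.M[:, cols] > 0
    state.z[:, cols] = np.where(obs, w, state.z[:, cols])
    return state


def beta_conditional_moments(
    state: PosteriorState, design
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of each column's beta full conditional.

    Returns ``(mean, cov)`` with shapes (n_c, n_cols) and (n_cols, n_c, n_c);
    conditioning is on the current Gamma, V, H, Lambda, sigma2 and the
    augmented responses.  With factors disabled and fixed variances this is
    the textbook Bayesian linear-regression posterior per column.
    """
    ws = _ws(design)
    Vinv = np.linalg.inv(state.V)
    ystar = _ystar(state, ws)
    R = (ystar - state.H @ state.Lambda) * ws.M
    mu = state.gamma @ ws.Ttilde.T                       # n_c x n_cols
    prec = Vinv[None] + ws.XtX_obs / state.sigma2[:, None, None]
    rhs = (Vinv @ mu).T + np.einsum("ik,ic->ck", ws.X, R) / state.sigma2[:, None]
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0].T
    cov = np.linalg.inv(prec)
    return mean, cov


def update_beta_gamma(state: PosteriorState, design, priors: PriorConfig, rng) -> PosteriorState:
    """Joint conjugate update of (Gamma, V, B)."""
    ws = _ws(design)
    rng = _as_rng(rng)
    n_c, q = state.gamma.shape
    n_cols = ws.n_cols

    # --- Gamma | B, V -------------------------------------------------------
    Vinv = np.linalg.inv(state.V)
    prec_g = np.eye(n_c * q) / priors.gamma_scale**2 + np.kron(ws.TtT, Vinv)
    rhs_g = (Vinv @ state.beta @ ws.Ttilde).flatten(order="F")
    _, gamma_vec = _sample_mvn_batch(prec_g[None], rhs_g[None], rng)
    state.gamma = gamma_vec[0].reshape(q, n_c).T

    # --- V | B, Gamma -------------------------------------------------------
    E = state.beta - state.gamma @ ws.Ttilde.T
    S = priors.v_scale * np.eye(n_c) + E @ E.T
    state.V = _inv_wishart(priors.v_df_for(n_c) + n_cols, S, rng)

    # --- B | rest -----------------------------------------------------------
    Vinv = np.linalg.inv(state.V)
    ystar = _ystar(state, ws)
    R = (ystar - state.H @ state.Lambda) * ws.M
    mu = state.gamma @ ws.Ttilde.T
    prec = Vinv[None] + ws.XtX_obs / state.sigma2[:, None, None]
    rhs = (Vinv @ mu).T + np.einsum("ik,ic->ck", ws.X, R) / state.sigma2[:, None]
    _, draw = _sample_mvn_batch(prec, rhs, rng)
    state.beta = draw.T
    return state


def update_factors(state: PosteriorState, design, priors: PriorConfig, rng) -> PosteriorState:
    """Factor scores, loadings and shrinkage parameters."""
    ws = _ws(design)
    rng = _as_rng(rng)
    n_f = state.H.shape[1]
    if n_f == 0:
        return state
    n_cols = ws.n_cols

    ystar = _ystar(state, ws)
    R = (ystar - ws.X @ state.beta) * ws.M
    W = ws.M / state.sigma2[None, :]

    # --- H rows -------------------------------------------------------------
    lam = state.Lambda
    prec_h = np.eye(n_f)[None] + np.einsum("kc,ic,lc->ikl", lam, W, lam)
    rhs_h = np.einsum("kc,ic->ik", lam, W * R)
    _, state.H = _sample_mvn_batch(prec_h, rhs_h, rng)

    # --- Lambda columns -----------------------------------------------------
    tau = state.tau
    prior_prec = state.psi * tau[:, None]                # n_f x n_cols
    HtH = np.einsum("ic,ik,il->ckl", W, state.H, state.H)
    prec_l = HtH + np.einsum("kc,kl->ckl", prior_prec, np.eye(n_f))
    rhs_l = np.einsum("ik,ic->ck", state.H, W * R)
    _, draw = _sample_mvn_batch(prec_l, rhs_l, rng)
    state.Lambda = draw.T

    # --- local shrinkage psi ------------------------------------------------
    lam2 = state.Lambda**2
    shape = 0.5 * (priors.nu + 1.0)
    rate = 0.5 * (priors.nu + tau[:, None] * lam2)
    state.psi = rng.gamma(shape, 1.0 / rate)

    # --- column multipliers delta (multiplicative gamma process) ------------
    s = np.sum(state.psi * lam2, axis=1)                 # n_f
    for h in range(n_f):
        d = state.delta.copy()
        d[h] = 1.0
        tau_minus = np.cumprod(d)
        a = priors.a1 if h == 0 else priors.a2
        b = priors.b1 if h == 0 else priors.b2
        shape_h = a + 0.5 * n_cols * (n_f - h)
        rate_h = b + 0.5 * np.sum(tau_minus[h:] * s[h:])
        state.delta[h] = rng.gamma(shape_h, 1.0 / rate_h)
    return state


def update_sigma(state: PosteriorState, design, priors: PriorConfig, rng) -> PosteriorState:
    """Inverse-gamma residual variance update per log-normal column."""
    ws = _ws(design)
    rng = _as_rng(rng)
    resid = (ws.Yf - ws.X @ state.beta - state.H @ state.Lambda) * ws.M
    sse = np.sum(resid**2, axis=0)
    shape = priors.sigma_shape + 0.5 * ws.n_obs
    rate = priors.sigma_rate + 0.5 * sse
    draw = 1.0 / rng.gamma(shape, 1.0 / rate)
    state.sigma2 = np.where(ws.is_probit, 1.0, draw)
    return state


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------
def _sweep(state: PosteriorState, ws: SamplerWorkspace, priors: PriorConfig, rng) -> PosteriorState:
    update_probit_latent(state, ws, rng)
    update_beta_gamma(state, ws, priors, rng)
    update_factors(state, ws, priors, rng)
    update_sigma(state, ws, priors, rng)
    return state


def run_mcmc(
    design: ModelDesign | SamplerWorkspace,
    priors: PriorConfig | None = None,
    chains: int = 4,
    iterations: int = 1000,
    burn_in: int = 0,
    thin: int = 1,
    seed: int | None = None,
    record_h: bool = True,
    progress_every: int = 0,
) -> PosteriorSampleSet:
    """Run the blocked Gibbs sweep and retain thinned post-burn-in states.

    Retained draws per chain = floor((iterations - burn_in) / thin); each
    chain gets an independent stream spawned from the master seed, and the
    spawned seeds are recorded in the output metadata.
    """
    if priors is None:
        priors = PriorConfig()
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    ws = _ws(design)
    n_keep = (iterations - burn_in) // thin
    if n_keep < 1:
        raise ValueError("no draws would be retained; lower thin or burn_in")

    master = np.random.SeedSequence(seed)
    children = master.spawn(chains)
    chain_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    n_f = priors.n_factors
    q = ws.Ttilde.shape[1]
    shape = (chains, n_keep)
    out = PosteriorSampleSet(
        beta=np.empty(shape + (ws.n_c, ws.n_cols)),
        gamma=np.empty(shape + (ws.n_c, q)),
        V=np.empty(shape + (ws.n_c, ws.n_c)),
        Lambda=np.empty(shape + (n_f, ws.n_cols)),
        sigma2=np.empty(shape + (ws.n_cols,)),
        H=np.empty(shape + (ws.n_sites, n_f)) if record_h else None,
        meta={
            "chains": chains,
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
            "chain_seeds": chain_seeds,
            "priors": priors.to_dict(),
            "n_factors": n_f,
        },
    )

    for ci, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = init_state(ws, priors, rng)
        kept = 0
        for it in range(iterations):
            _sweep(state, ws, priors, rng)
            if it >= burn_in and (it - burn_in + 1) % thin == 0 and kept < n_keep:
                if not (np.all(np.isfinite(state.beta)) and np.all(np.isfinite(state.Lambda))
                        and np.all(np.isfinite(state.sigma2))):
                    raise RuntimeError(f"non-finite state at chain {ci}, iteration {it}")
                out.beta[ci, kept] = state.beta
                out.gamma[ci, kept] = state.gamma
                out.V[ci, kept] = state.V
                out.Lambda[ci, kept] = state.Lambda
                out.sigma2[ci, kept] = state.sigma2
                if record_h:
                    out.H[ci, kept] = state.H
                kept += 1
            if progress_every and (it + 1) % progress_every == 0:
                logger.info("chain %d: iteration %d/%d", ci, it + 1, iterations)
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------
def convergence_diagnostics(
    samples: PosteriorSampleSet,
    include_omega: bool = True,
    max_omega_entries: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> "pd.DataFrame":
    """Split-chain R-hat and effective sample size per parameter block.

    Covers the environmental responses B, trait effects Gamma and (optionally
    a subsample of) association-matrix entries; loadings and factor scores
    are excluded because their sign/rotation is not identified.
    """
    import pandas as pd
    import arviz as az

    if samples.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")

    rows = []

    def _block(name: str, arr: np.ndarray, labels: Sequence[str]):
        ds = az.convert_to_dataset({name: arr})
        rhat = az.rhat(ds)[name].to_numpy().ravel()
        ess = az.ess(ds)[name].to_numpy().ravel()
        for lab, r, e in zip(labels, rhat, ess):
            rows.append({"block": name, "param": lab, "rhat": float(r), "ess_bulk": float(e)})

    C, D = samples.n_chains, samples.n_draws_per_chain
    beta = samples.beta.reshape(C, D, -1)
    _block("beta", beta, [f"beta[{i}]" for i in range(beta.shape[2])])
    gamma = samples.gamma.reshape(C, D, -1)
    _block("gamma", gamma, [f"gamma[{i}]" for i in range(gamma.shape[2])])

    if include_omega and samples.n_factors > 0:
        p = samples.Lambda.shape[3]
        iu = np.triu_indices(p)
        n_entries = len(iu[0])
        if n_entries > max_omega_entries:
            r = _as_rng(rng)
            pick = r.choice(n_entries, size=max_omega_entries, replace=False)
            iu = (iu[0][pick], iu[1][pick])
        ent = np.sum(
            samples.Lambda[:, :, :, iu[0]] * samples.Lambda[:, :, :, iu[1]], axis=2
        )
        _block("omega", ent, [f"omega[{a},{b}]" for a, b in zip(iu[0], iu[1])])

    return pd.DataFrame(rows)
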