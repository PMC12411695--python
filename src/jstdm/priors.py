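"""Prior configuration for the latent-factor model.

Defaults follow the published defaults of the HMSC model family: independent
standard-normal priors on the trait effects, an inverse-Wishart prior on the
covariance of the species-specific deviations of the environmental responses,
a multiplicative gamma process shrinkage prior on the factor loadings
(ordered shrinkage: later factors are pulled harder towards zero) and
inverse-gamma priors on the log-normal residual variances.  Every value is
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["PriorConfig"]


@dataclass
class PriorConfig:
    """Hyperparameters of the hierarchical prior.

    Parameters
    ----------
    gamma_scale : float
        Prior SD of each trait effect (prior N(0, gamma_scale² I)).
    v_df : float or None
        Inverse-Wishart degrees of freedom for the residual covariance V of
        the environmental responses; ``None`` means n_covariates + 1.
    v_scale : float
        Inverse-Wishart scale matrix multiplier (scale = v_scale · I).
    nu : float
        Local shrinkage degrees of freedom (per-loading gamma(nu/2, nu/2)).
    a1, b1 : float
        Shape/rate of the first column-shrinkage multiplier.
    a2, b2 : float
        Shape/rate of the subsequent multipliers.
    sigma_shape, sigma_rate : float
        Inverse-gamma shape/rate for log-normal residual variances.
    n_factors : int
        Number of latent factors (fixed truncation; the shrinkage prior makes
        surplus factors vanish).  0 disables the factor block.
    """

    gamma_scale: float = 1.0
    v_df: float | None = None
    v_scale: float = 1.0
    nu: float = 3.0
    a1: float = 50.0
    b1: float = 1.0
    a2: float = 50.0
    b2: float = 1.0
    sigma_shape: float = 1.0
    sigma_rate: float = 0.1
    n_factors: int = 5

    def __post_init__(self) -> None:
        for name in ("gamma_scale", "v_scale", "nu", "a1", "b1", "a2", "b2",
                     "sigma_shape", "sigma_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.v_df is not None and self.v_df <= 0:
            raise ValueError("v_df must be strictly positive")
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")

    def v_df_for(self, n_covariates: int) -> float:
        return float(self.v_df) if self.v_df is not None else n_covariates + 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    def delta_prior_means(self) -> np.ndarray:
        """Prior mean of each column-shrinkage multiplier (ordered shrinkage)."""
        means = np.full(self.n_factors, self.a2 / self.b2)
        if self.n_factors:
            means[0] = self.a1 / self.b1
        return means
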