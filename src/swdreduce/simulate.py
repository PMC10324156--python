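"""Monte-Carlo simulator for the outcome model on cluster-period means.

Outcomes follow the linear mixed model with overall mean mu, fixed period
effects beta_j (beta_1 = 0 for identifiability), treatment effect theta,
cluster(-period) random effects with covariance tau2 * R, and iid
individual error. Because the GLS analysis operates on cluster-period
means, the simulator draws the means directly: averaging m individual
errors shrinks the error variance to sigma2_eps / m, so

    Ybar_kj = mu + beta_j + X_kj * theta + gamma_kj + ebar_kj,
    gamma_k ~ N_T(0, tau2 R),  ebar_kj ~ N(0, sigma2_eps / m).

Used as the simulation oracle for the closed-form design variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DesignConfig
from .covariance import CovarianceModel, build_R
from .design import Design


@dataclass(frozen=True)
class OutcomeModel:
    """Mean structure plus variance components of the outcome model."""

    mu: float
    beta: np.ndarray  # length T, beta[0] == 0
    theta: float
    covariance: CovarianceModel

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta[0] != 0.0:
            raise ValueError("beta_1 must be 0 for identifiability")
        beta.setflags(write=False)
        object.__setattr__(self, "beta", beta)

    @classmethod
    def from_config(
        cls, config: DesignConfig, mu: float = 0.0, beta: np.ndarray | None = None
    ) -> "OutcomeModel":
        if beta is None:
            beta = np.zeros(config.T)
        return cls(mu, beta, config.effect_size, CovarianceModel.from_config(config))


def simulate_cluster_period_means(
    model: OutcomeModel,
    design: Design,
    m: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw replicate cluster-period mean outcomes for a design.

    Returns an array of shape ``(n_replicates, K, T)`` with NaN in
    unobserved cells.
    """
    K, T = design.K, design.T
    cov = model.covariance
    R = build_R(T, cov.r, cov.structure)
    L = np.linalg.cholesky(cov.tau2 * R + 1e-15 * np.eye(T))
    mean = model.mu + model.beta[None, :] + model.theta * design.X
    gamma = rng.standard_normal((n_replicates, K, T)) @ L.T
    ebar = rng.standard_normal((n_replicates, K, T)) * np.sqrt(cov.sigma2_eps / m)
    y = mean[None, :, :] + gamma + ebar
    y[:, ~design.observed] = np.nan
    return y
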