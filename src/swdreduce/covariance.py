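"""Covariance of cluster-period means under the supported correlation structures.

Outcomes follow a linear mixed model with fixed categorical period effects,
a treatment effect, cluster(-period) random effects and individual error.
Collapsing to cluster-period means, the within-cluster covariance matrix is

    V = (sigma2_eps / m) * I + tau2 * R,

where ``R`` is the correlation matrix of the cluster-period random effects:
all ones (exchangeable, a shared cluster random intercept), ``r**|j-s|``
(discrete-time decay), or ``r`` off the unit diagonal (block-exchangeable).

Variance components follow the unit-total-variance convention
``tau2 + sigma2_eps = 1`` so that ``tau2`` equals the within-period ICC
``rho`` and effect sizes are on the total-SD scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, CorrelationStructure, DesignConfig


@dataclass(frozen=True)
class CovarianceModel:
    """Variance components of the outcome model.

    ``tau2`` is the cluster-level variance, ``sigma2_eps`` the
    individual-level error variance, ``r`` the cluster autocorrelation.
    """

    tau2: float
    sigma2_eps: float
    r: float
    structure: CorrelationStructure

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ConfigurationError(f"tau2 must be >= 0, got {self.tau2}")
        if self.sigma2_eps <= 0:
            raise ConfigurationError(f"sigma2_eps must be > 0, got {self.sigma2_eps}")
        object.__setattr__(self, "structure", CorrelationStructure(self.structure))

    @classmethod
    def from_config(cls, config: DesignConfig) -> "CovarianceModel":
        return cls(config.tau2, config.sigma2_eps, config.r, config.structure)


def build_R(T: int, r: float, structure: CorrelationStructure | str) -> np.ndarray:
    """Correlation matrix of the cluster-period random effects.

    discrete_time_decay: ``R[j, s] = r**|j - s|``; exchangeable: all ones
    (requires or implies ``r = 1``); block_exchangeable: unit diagonal with
    ``r`` everywhere off-diagonal.
    """
    if not 0.0 < r <= 1.0:
        raise ConfigurationError(f"r must lie in (0, 1], got {r}")
    structure = CorrelationStructure(structure)
    if structure is CorrelationStructure.EXCHANGEABLE:
        return np.ones((T, T))
    if structure is CorrelationStructure.DISCRETE_TIME_DECAY:
        idx = np.arange(T)
        return r ** np.abs(idx[:, None] - idx[None, :]).astype(float)
    R = np.full((T, T), r)
    np.fill_diagonal(R, 1.0)
    return R


def cluster_covariance(model: CovarianceModel, m: int, T: int) -> np.ndarray:
    """``T x T`` covariance matrix of a cluster's period means.

    ``V = (sigma2_eps / m) I + tau2 R``. The identity shift bounds every
    eigenvalue below by ``sigma2_eps / m``, so V is symmetric positive
    definite for all valid parameters.
    """
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    R = build_R(T, model.r, model.structure)
    V = (model.sigma2_eps / m) * np.eye(T) + model.tau2 * R
    # defensive: cannot fail for valid parameters
    assert np.all(np.linalg.eigvalsh(V) > 0), "cluster covariance not PD"
    return V


def cluster_covariance_from_config(config: DesignConfig) -> np.ndarray:
    """Convenience: V for the configuration's variance components."""
    return cluster_covariance(CovarianceModel.from_config(config), config.m, config.T)


def build_Z(observed_periods: np.ndarray, T: int) -> np.ndarray:
    """``T_k x T`` period-selection matrix for one cluster.

    Rows of the ``T x T`` identity corresponding to unobserved periods are
    deleted; ``observed_periods`` holds the 0-based indices of the observed
    periods in increasing order.
    """
    obs = np.asarray(observed_periods, dtype=int)
    if obs.size == 0:
        raise ValueError("observed_periods must be nonempty")
    if np.any(np.diff(obs) <= 0):
        raise ValueError("observed_periods must be strictly increasing")
    return np.eye(T)[obs]


def restrict_to_observed(V: np.ndarray, observed_periods: np.ndarray) -> np.ndarray:
    """``V_k = Z V Z^T``: the covariance submatrix of the observed periods."""
    obs = np.asarray(observed_periods, dtype=int)
    return V[np.ix_(obs, obs)]
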