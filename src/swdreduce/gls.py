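"""Variance of the GLS treatment effect estimator for stepped wedge designs.

At the design stage the correlation structure and its parameters are taken
as known, so the treatment effect is estimated by generalised least squares
on the cluster-period means and its variance is available in closed form.
For a complete design with common cluster covariance ``V``,

    var(theta_hat) = { sum_k X_k' V^-1 X_k
                       - (1/K) (sum_k X_k)' V^-1 (sum_k X_k) }^-1,

where ``X_k`` is cluster k's vector of treatment indicators. For incomplete
designs each cluster contributes only its observed periods: with ``Z_k`` the
period-selection matrix, ``V_k = Z_k V Z_k'`` and ``X_k`` restricted to the
observed periods,

    var(theta_hat) = { sum_k X_k' V_k^-1 X_k - c' B^-1 c }^-1,
    c = sum_k Z_k' V_k^-1 X_k,   B = sum_k Z_k' V_k^-1 Z_k,

which reduces to the complete-design expression when every cell is observed.
The treatment effect is estimable only if some period contains both an
observed control cell and an observed intervention cell; designs failing
that condition, or for which the bracketed scalar is numerically singular,
are reported as non-estimable (a value, not an exception — the removal
algorithm probes many non-estimable candidates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .config import DesignConfig
from .covariance import cluster_covariance_from_config
from .design import Design

# Relative eigenvalue threshold below which the time-effect information
# matrix is treated as singular, and relative floor for the bracket scalar.
_SINGULAR_RTOL = 1e-12
_SCALAR_RTOL = 1e-9


@dataclass(frozen=True)
class VarianceResult:
    """var(theta_hat), its reciprocal, and whether the effect is estimable.

    A non-estimable design carries ``variance = inf`` and ``information = 0``.
    """

    variance: float
    estimable: bool

    @property
    def information(self) -> float:
        return 0.0 if not self.estimable else 1.0 / self.variance

    @classmethod
    def non_estimable(cls) -> "VarianceResult":
        return cls(math.inf, False)


def _has_within_period_contrast(X: np.ndarray, observed: np.ndarray) -> bool:
    """Necessary condition for estimability: some period holds both an
    observed control cell and an observed intervention cell."""
    treated = observed & (X == 1)
    control = observed & (X == 0)
    return bool(np.any(treated.any(axis=0) & control.any(axis=0)))


def _variance_from_parts(X: np.ndarray, observed: np.ndarray, V: np.ndarray) -> VarianceResult:
    """Incomplete-design GLS variance from raw arrays and a precomputed V.

    Clusters with no observed periods contribute nothing. All solves are
    Cholesky-based; no explicit inverse of V is formed for the quadratic
    forms (the per-cluster precision blocks accumulated into B require
    solving against the identity, done through the same factorisation).
    """
    if not _has_within_period_contrast(X, observed):
        return VarianceResult.non_estimable()
    K, T = X.shape
    A = 0.0
    c = np.zeros(T)
    B = np.zeros((T, T))
    for k in range(K):
        idx = np.flatnonzero(observed[k])
        if idx.size == 0:
            continue
        Vk = V[np.ix_(idx, idx)]
        Xk = X[k, idx].astype(float)
        factor = cho_factor(Vk, lower=True)
        vx = cho_solve(factor, Xk)
        A += float(Xk @ vx)
        c[idx] += vx
        B[np.ix_(idx, idx)] += cho_solve(factor, np.eye(idx.size))
    periods = np.flatnonzero(observed.any(axis=0))
    BJ = B[np.ix_(periods, periods)]
    cJ = c[periods]
    eig = np.linalg.eigvalsh(BJ)
    if eig[0] <= _SINGULAR_RTOL * max(eig[-1], 1.0):
        return VarianceResult.non_estimable()
    try:
        sol = cho_solve(cho_factor(BJ, lower=True), cJ)
    except LinAlgError:
        return VarianceResult.non_estimable()
    q = A - float(cJ @ sol)
    if q <= _SCALAR_RTOL * max(A, 1.0):
        return VarianceResult.non_estimable()
    return VarianceResult(1.0 / q, True)


def variance_complete(design: Design, V: np.ndarray) -> VarianceResult:
    """Complete-design GLS variance of the treatment effect estimator.

    Requires every cell observed and a common cluster covariance ``V``.
    """
    if not design.observed.all():
        raise ValueError("variance_complete requires every cell observed")
    X = design.X.astype(float)
    K = design.K
    if not _has_within_period_contrast(design.X, design.observed):
        return VarianceResult.non_estimable()
    factor = cho_factor(V, lower=True)
    A = 0.0
    for k in range(K):
        A += float(X[k] @ cho_solve(factor, X[k]))
    s = X.sum(axis=0)
    q = A - float(s @ cho_solve(factor, s)) / K
    if q <= _SCALAR_RTOL * max(A, 1.0):
        return VarianceResult.non_estimable()
    return VarianceResult(1.0 / q, True)


def variance_incomplete(
    design: Design, config: DesignConfig, V: np.ndarray | None = None
) -> VarianceResult:
    """GLS variance valid for complete and incomplete stepped wedge designs.

    ``V`` may be supplied to avoid rebuilding the cluster covariance in
    inner loops; it must equal ``cluster_covariance_from_config(config)``.
    """
    if V is None:
        V = cluster_covariance_from_config(config)
    return _variance_from_parts(design.X, design.observed, V)


def is_estimable(design: Design, config: DesignConfig) -> bool:
    """Whether the treatment effect has a finite GLS variance for ``design``.

    Consistency with the necessary within-period-contrast condition is
    asserted: an estimable design always exhibits a period with both an
    observed control and an observed intervention cell.
    """
    result = variance_incomplete(design, config)
    if result.estimable:
        assert _has_within_period_contrast(design.X, design.observed)
    return result.estimable
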