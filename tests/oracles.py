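"""Independent oracles used by the test suite.

Both routes below compute the variance of the GLS treatment effect
estimator without going through the package's incomplete-design formula:

* ``hussey_hughes_variance`` is the classic closed form for complete
  stepped wedge designs under the exchangeable structure, written directly
  from the published scalar formula.
* ``stacked_gls_variance`` assembles the full fixed-effects information
  matrix of the cluster-period-mean model (intercept, period effects,
  treatment) cluster by cluster and reads off the treatment component of
  its inverse. It is valid for any structure and any observation mask.
"""

from __future__ import annotations

import numpy as np

from swdreduce import Design, DesignConfig, cluster_covariance_from_config


def hussey_hughes_variance(X: np.ndarray, m: int, rho: float) -> float:
    """Closed-form complete-design variance, exchangeable structure.

    ``X`` is the K x T treatment indicator matrix. Uses the unit-total-
    variance convention: tau2 = rho, individual error 1 - rho, so the
    cell-mean error variance is sigma2 = (1 - rho) / m.
    """
    K, T = X.shape
    sigma2 = (1.0 - rho) / m
    tau2 = rho
    U = X.sum()
    W = (X.sum(axis=0) ** 2).sum()
    V = (X.sum(axis=1) ** 2).sum()
    num = K * sigma2 * (sigma2 + T * tau2)
    den = (K * U - W) * sigma2 + (U**2 + K * T * U - T * W - K * V) * tau2
    return num / den


def stacked_gls_variance(design: Design, config: DesignConfig) -> float:
    """Treatment-effect variance from the full stacked mean model.

    Fixed effects: intercept, one indicator per non-reference observed
    period, and the treatment indicator. Returns the (theta, theta) entry
    of the inverse information matrix. Raises LinAlgError if the
    information matrix is singular (treatment effect not estimable).
    """
    V = cluster_covariance_from_config(config)
    periods = np.flatnonzero(design.observed.any(axis=0))
    ref = periods[0]
    dummy_periods = [p for p in periods if p != ref]
    p = 2 + len(dummy_periods)  # intercept + period dummies + treatment
    M = np.zeros((p, p))
    for k in range(design.K):
        idx = np.flatnonzero(design.observed[k])
        if idx.size == 0:
            continue
        D = np.zeros((idx.size, p))
        D[:, 0] = 1.0
        for col, per in enumerate(dummy_periods, start=1):
            D[:, col] = idx == per
        D[:, -1] = design.X[k, idx]
        Vk = V[np.ix_(idx, idx)]
        M += D.T @ np.linalg.solve(Vk, D)
    return float(np.linalg.inv(M)[-1, -1])
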