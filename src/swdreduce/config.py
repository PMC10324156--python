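"""Trial configuration for stepped wedge designs.

A standard stepped wedge over ``T`` periods has one cluster per treatment
sequence, hence ``K = T - 1`` clusters: cluster ``k`` (1-based) crosses from
control to intervention at the start of period ``k + 1``, so every cluster
starts in control and all are treated by the final period.

Correlation between outcomes within a cluster is parameterised by the
within-period intracluster correlation ``rho`` and the cluster
autocorrelation ``r`` (the proportionate drop in correlation per period of
separation). ``r = 1`` gives the exchangeable structure; ``r < 1`` with
geometric decay gives the discrete-time decay structure; block-exchangeable
keeps a flat between-period correlation ``rho * r``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class CorrelationStructure(str, enum.Enum):
    """Within-cluster correlation structure of cluster-period random effects."""

    EXCHANGEABLE = "exchangeable"
    BLOCK_EXCHANGEABLE = "block_exchangeable"
    DISCRETE_TIME_DECAY = "discrete_time_decay"


class ConfigurationError(ValueError):
    """A trial configuration parameter is out of its valid range."""


@dataclass(frozen=True)
class DesignConfig:
    """Immutable stepped wedge trial configuration.

    Parameters
    ----------
    T
        Number of measurement periods (>= 2). The number of clusters is
        fixed at ``K = T - 1``, one per sequence.
    m
        Number of subjects measured per observed cluster-period cell (>= 1).
    rho
        Within-period intracluster correlation, in ``[0, 1)``.
    r
        Cluster autocorrelation, in ``(0, 1]``. Must be 1 for the
        exchangeable structure.
    structure
        One of :class:`CorrelationStructure` (or its string value).
    effect_size
        Standardised treatment effect, in units of the total outcome
        standard deviation.
    alpha
        Two-sided significance level for power calculations, in ``(0, 1)``.
    """

    T: int
    m: int
    rho: float
    r: float = 1.0
    structure: CorrelationStructure = CorrelationStructure.EXCHANGEABLE
    effect_size: float = 0.25
    alpha: float = 0.05
    K: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", CorrelationStructure(self.structure))
        if int(self.T) != self.T or self.T < 2:
            raise ConfigurationError(f"T must be an integer >= 2, got {self.T}")
        if int(self.m) != self.m or self.m < 1:
            raise ConfigurationError(f"m must be an integer >= 1, got {self.m}")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 < self.r <= 1.0:
            raise ConfigurationError(f"r must lie in (0, 1], got {self.r}")
        if self.structure is CorrelationStructure.EXCHANGEABLE and self.r != 1.0:
            raise ConfigurationError(
                "exchangeable structure requires r = 1 "
                f"(got r = {self.r}); use discrete_time_decay or "
                "block_exchangeable for r < 1"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        object.__setattr__(self, "T", int(self.T))
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "K", self.T - 1)

    @property
    def tau2(self) -> float:
        """Cluster-level variance component under the unit-total-variance
        convention (``tau2 + sigma2_eps = 1``), i.e. ``tau2 = rho``."""
        return self.rho

    @property
    def sigma2_eps(self) -> float:
        """Individual-level error variance under the unit-total-variance
        convention, i.e. ``1 - rho``."""
        return 1.0 - self.rho
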