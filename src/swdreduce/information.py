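"""Information content of centrosymmetric cell pairs.

The information content (IC) of a pair of cells A within a design D is the
ratio of treatment-effect-estimator variances

    IC_D(A) = var_{D[A]}(theta_hat) / var_D(theta_hat),

where D[A] is D with both cells of A removed. IC >= 1 always (GLS on a
subset of the data cannot be more precise), and IC is equal for the two
members of a centrosymmetric pair, so the per-cell IC map is itself
centrosymmetric. IC = +inf encodes "removing this pair breaks estimability".

IC is computed by direct re-evaluation of the incomplete-design variance on
each reduced design rather than by a rank-one precision update; at the
design sizes of interest (T up to a few tens) this costs milliseconds and
avoids a class of incremental-update bugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DesignConfig
from .covariance import cluster_covariance_from_config
from .design import CellPair, Design, enumerate_pairs, remove_pair
from .gls import variance_incomplete


@dataclass(frozen=True)
class ICMap:
    """Per-cell information content for one design.

    ``values`` is a ``K x T`` float array holding each observed cell's pair
    IC (NaN for unobserved cells; +inf where removal breaks estimability);
    both members of a pair share one value. ``base_variance`` is
    var(theta_hat) of the design itself.
    """

    values: np.ndarray
    base_variance: float
    pair_ic: dict[CellPair, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-ready frame: clusters as rows, periods as columns."""
        K, T = self.values.shape
        return pd.DataFrame(
            self.values,
            index=pd.RangeIndex(1, K + 1, name="cluster"),
            columns=pd.RangeIndex(1, T + 1, name="period"),
        )

    def to_long_frame(self, design: Design) -> pd.DataFrame:
        """Long-format frame with one row per cell."""
        rows = []
        for k in range(1, design.K + 1):
            for j in range(1, design.T + 1):
                rows.append(
                    {
                        "cluster": k,
                        "period": j,
                        "ic": self.values[k - 1, j - 1],
                        "observed": bool(design.observed[k - 1, j - 1]),
                        "treatment": int(design.X[k - 1, j - 1]),
                    }
                )
        return pd.DataFrame(rows)


def pair_ic(
    design: Design,
    pair: CellPair,
    config: DesignConfig,
    *,
    V: np.ndarray | None = None,
    base_variance: float | None = None,
) -> float:
    """IC of ``pair`` within ``design``; +inf if removal breaks estimability.

    ``V`` and ``base_variance`` may be supplied to avoid recomputation in
    loops over many pairs.
    """
    if V is None:
        V = cluster_covariance_from_config(config)
    if base_variance is None:
        base = variance_incomplete(design, config, V)
        if not base.estimable:
            raise ValueError("base design is not estimable")
        base_variance = base.variance
    reduced = variance_incomplete(remove_pair(design, pair), config, V)
    if not reduced.estimable:
        return math.inf
    return reduced.variance / base_variance


def ic_map(design: Design, config: DesignConfig) -> ICMap:
    """Evaluate pair IC for every observed pair and fill both member cells."""
    V = cluster_covariance_from_config(config)
    base = variance_incomplete(design, config, V)
    if not base.estimable:
        raise ValueError("base design is not estimable")
    values = np.full((design.K, design.T), np.nan)
    ics: dict[CellPair, float] = {}
    for pair in enumerate_pairs(design):
        ic = pair_ic(design, pair, config, V=V, base_variance=base.variance)
        ics[pair] = ic
        for k, j in pair.cells():
            values[k - 1, j - 1] = ic
    return ICMap(values, base.variance, ics)
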