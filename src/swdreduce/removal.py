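"""Greedy iterative removal of low-information cell pairs.

Starting from the complete stepped wedge design, each iteration computes
the information content (IC) of every remaining centrosymmetric pair,
removes the pair with the lowest finite IC, and repeats until no removal
leaves the treatment effect estimable. The final design on the path is the
*minimally viable design*. Ties in IC (the exchangeable structure produces
exact mathematical ties that differ only in the last floating-point bits)
are broken toward the pair whose top-left member has the smallest
(cluster, period) index.

The full trace — every intermediate design, its IC map, variance, precision
loss and power — is retained; memory is trivial at these design sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, DesignConfig
from .design import CellPair, Design, build_complete_sw, remove_pair
from .gls import variance_incomplete
from .information import ICMap, ic_map
from . import metrics

# ICs within this relative tolerance are treated as tied.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class RemovalStep:
    """One design along the removal path.

    ``removed_pair`` is the pair removed *from this design* to produce the
    next one; it is None on the final (minimally viable) design.
    """

    iteration: int
    design: Design
    icmap: ICMap
    removed_pair: CellPair | None
    variance: float
    precision_loss_pct: float
    power_pct: float


@dataclass(frozen=True)
class RemovalTrace:
    """Ordered record of the whole removal path for one configuration."""

    steps: list[RemovalStep]
    config: DesignConfig

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def complete_design(self) -> Design:
        return self.steps[0].design

    @property
    def final_design(self) -> Design:
        return self.steps[-1].design

    @property
    def variances(self) -> np.ndarray:
        return np.array([s.variance for s in self.steps])

    def step_at_removed_pairs(self, n_pairs: int) -> RemovalStep:
        """The design after exactly ``n_pairs`` pair removals."""
        return self.steps[n_pairs]

    def to_frame(self) -> pd.DataFrame:
        """Per-iteration tidy frame (one row per design on the path)."""
        rows = []
        for s in self.steps:
            pair = s.removed_pair
            rows.append(
                {
                    "iteration": s.iteration,
                    "removed_cluster": pair.cell_a[0] if pair else pd.NA,
                    "removed_period": pair.cell_a[1] if pair else pd.NA,
                    "partner_cluster": pair.cell_b[0] if pair else pd.NA,
                    "partner_period": pair.cell_b[1] if pair else pd.NA,
                    "n_cells_remaining": s.design.n_observed,
                    "pct_removed": s.design.pct_removed,
                    "variance": s.variance,
                    "precision_loss_pct": s.precision_loss_pct,
                    "power_pct": s.power_pct,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-ready bundle of all designs and IC maps on the path."""
        return {
            "config": {
                "T": self.config.T,
                "m": self.config.m,
                "rho": self.config.rho,
                "r": self.config.r,
                "structure": self.config.structure.value,
                "effect_size": self.config.effect_size,
                "alpha": self.config.alpha,
            },
            "steps": [
                {
                    "iteration": s.iteration,
                    "design": s.design.to_dict(),
                    "ic": [
                        [None if not math.isfinite(v) else v for v in row]
                        for row in s.icmap.values.tolist()
                    ],
                    "removed_pair": (
                        None
                        if s.removed_pair is None
                        else [list(s.removed_pair.cell_a), list(s.removed_pair.cell_b)]
                    ),
                    "variance": s.variance,
                    "precision_loss_pct": s.precision_loss_pct,
                    "power_pct": s.power_pct,
                }
                for s in self.steps
            ],
        }


def select_min_pair(icmap: ICMap, pairs: list[CellPair]) -> CellPair | None:
    """Pair with minimum finite IC, ties broken toward the top-left corner.

    Returns None when every pair has infinite IC, signalling termination.
    ``pairs`` must be sorted by their lexicographically smaller member (as
    produced by ``enumerate_pairs``); among ICs within relative tolerance of
    the minimum the earliest pair in that order wins.
    """
    finite = [(icmap.pair_ic[p], p) for p in pairs if math.isfinite(icmap.pair_ic[p])]
    if not finite:
        return None
    min_ic = min(ic for ic, _ in finite)
    for ic, pair in sorted(finite, key=lambda t: t[1].cell_a):
        if ic <= min_ic * (1.0 + _TIE_RTOL):
            return pair
    raise AssertionError("unreachable: minimum not found")


def run_removal(config: DesignConfig) -> RemovalTrace:
    """Run the greedy pair-removal algorithm from the complete design.

    Each step records the current design, its IC map, variance, precision
    loss relative to the complete design, and power for the configured
    effect size. Terminates when no pair removal preserves estimability.

    Raises ConfigurationError when the complete design itself cannot
    estimate the treatment effect; this happens only at T = 2, where the
    two cell means cannot separate the treatment effect from the period
    effect.
    """
    design = build_complete_sw(config)
    base = variance_incomplete(design, config)
    if not base.estimable:
        raise ConfigurationError(
            f"the complete T={config.T} stepped wedge cannot estimate the "
            "treatment effect (no period contrasts the two arms); "
            "the smallest reducible design has T = 3"
        )
    var0 = base.variance

    steps: list[RemovalStep] = []
    variance = var0
    while True:
        current_map = ic_map(design, config)
        pairs = [p for p in current_map.pair_ic]
        chosen = select_min_pair(current_map, pairs) if pairs else None
        steps.append(
            RemovalStep(
                iteration=len(steps),
                design=design,
                icmap=current_map,
                removed_pair=chosen,
                variance=variance,
                precision_loss_pct=metrics.precision_loss(var0, variance),
                power_pct=metrics.power(variance, config.effect_size, config.alpha),
            )
        )
        if chosen is None:
            break
        design = remove_pair(design, chosen)
        assert design.is_centrosymmetric() and design.is_skew_symmetric()
        result = variance_incomplete(design, config)
        assert result.estimable, "selected pair must preserve estimability"
        assert result.variance >= variance * (1.0 - 1e-9), "variance must not decrease"
        variance = result.variance
    return RemovalTrace(steps, config)
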