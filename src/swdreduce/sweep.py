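"""Parameter sweep of precision loss at fixed removal checkpoints.

For every combination of periods, cluster-period size, within-period ICC
and cluster autocorrelation on a grid, run the full removal path and record
the precision loss at the designs where a given percentage of cells has
been removed. The default grid covers 36 configurations: T in {5, 10}, m in
{10, 100}, rho in {0.01, 0.05, 0.15}, r in {1, 0.95, 0.8} (r = 1 is the
exchangeable structure, r < 1 discrete-time decay), with checkpoints at
20%, 50% and 80% of cells removed.

Cells leave the design in pairs, so a checkpoint percentage is realised as
``ceil(pct/100 * K*T / 2)`` pair removals: exact for the 5-period design
(20 cells), while for the 10-period design (90 cells) the 50% checkpoint
lands on 46 cells removed (51.11%, i.e. 48.89% of cells remaining).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from .config import CorrelationStructure, DesignConfig
from .removal import RemovalTrace, run_removal


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian grid of trial configurations plus removal checkpoints."""

    periods: tuple[int, ...] = (5, 10)
    m: tuple[int, ...] = (10, 100)
    rho: tuple[float, ...] = (0.01, 0.05, 0.15)
    r: tuple[float, ...] = (1.0, 0.95, 0.8)
    checkpoints_pct: tuple[float, ...] = (20.0, 50.0, 80.0)

    def configs(self) -> list[DesignConfig]:
        out = []
        for T, m, rho, r in itertools.product(self.periods, self.m, self.rho, self.r):
            structure = (
                CorrelationStructure.EXCHANGEABLE
                if r == 1.0
                else CorrelationStructure.DISCRETE_TIME_DECAY
            )
            out.append(DesignConfig(T=T, m=m, rho=rho, r=r, structure=structure))
        return out


def pairs_for_checkpoint(T: int, pct: float) -> int:
    """Number of pair removals realising a cell-removal percentage."""
    n_cells = T * (T - 1)
    return math.ceil(pct / 100.0 * n_cells / 2.0)


def run_sweep(grid: SweepGrid | None = None) -> pd.DataFrame:
    """Run removal paths over the grid; one row per config x checkpoint.

    Columns: T, m, rho, r, structure, checkpoint_pct, n_pairs_removed,
    actual_pct_removed, precision_loss_pct, reached. A checkpoint the path
    terminates before is flagged ``reached = False`` with NaN loss.
    """
    if grid is None:
        grid = SweepGrid()
    rows = []
    for config in grid.configs():
        trace: RemovalTrace = run_removal(config)
        for pct in grid.checkpoints_pct:
            n_pairs = pairs_for_checkpoint(config.T, pct)
            reached = n_pairs < len(trace)
            if reached:
                step = trace.step_at_removed_pairs(n_pairs)
                actual = step.design.pct_removed
                loss = step.precision_loss_pct
            else:
                actual = float("nan")
                loss = float("nan")
            rows.append(
                {
                    "T": config.T,
                    "m": config.m,
                    "rho": config.rho,
                    "r": config.r,
                    "structure": config.structure.value,
                    "checkpoint_pct": pct,
                    "n_pairs_removed": n_pairs,
                    "actual_pct_removed": actual,
                    "precision_loss_pct": loss,
                    "reached": reached,
                }
            )
    return pd.DataFrame(rows)


def summarise_sweep(result: pd.DataFrame) -> dict:
    """Per-checkpoint min/max precision loss over reached configurations."""
    summary = {}
    for pct, group in result[result["reached"]].groupby("checkpoint_pct"):
        summary[f"checkpoint_{pct:g}"] = {
            "min_precision_loss_pct": float(group["precision_loss_pct"].min()),
            "max_precision_loss_pct": float(group["precision_loss_pct"].max()),
            "n_configs": int(len(group)),
        }
    return summary
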