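"""Stepped wedge design schematics and centrosymmetric cell pairs.

A design is a ``K x T`` grid of cluster-period cells. Each cell carries a
treatment indicator (0 = control, 1 = intervention) and an observation flag
(measured or not). The complete standard stepped wedge observes every cell;
incomplete designs are obtained by switching off cells in *centrosymmetric
pairs* — cell ``(k, j)`` together with cell ``(K+1-k, T+1-j)``, its image
under reflecting the schematic through its centre. Removing cells only in
such pairs preserves two structural properties:

* **centrosymmetry** of the observation mask, and
* **skew-symmetry**: wherever both members of a pair are observed, their
  treatment labels are complementary.

Indices are 1-based in all user-facing representations (cluster 1 is the
first row, period 1 the first column); internal arrays are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .config import ConfigurationError, DesignConfig

Cell = tuple[int, int]  # (cluster k, period j), 1-based


class StructuralError(ValueError):
    """A design violates the centrosymmetric-mask or skew-symmetry invariant."""


@dataclass(frozen=True, order=True)
class CellPair:
    """A centrosymmetric pair of cluster-period cells (1-based indices).

    ``cell_a`` is always the lexicographically smaller member, so pairs sort
    by the position of the cell closest to the top-left corner.
    """

    cell_a: Cell
    cell_b: Cell

    @classmethod
    def from_cell(cls, cell: Cell, K: int, T: int) -> "CellPair":
        other = centrosymmetric_partner(cell, K, T)
        a, b = sorted((cell, other))
        return cls(a, b)

    def cells(self) -> Iterator[Cell]:
        yield self.cell_a
        yield self.cell_b


def centrosymmetric_partner(cell: Cell, K: int, T: int) -> Cell:
    """Return the centrosymmetric partner ``(K+1-k, T+1-j)`` of ``(k, j)``.

    The partnering is an involution; with ``K = T - 1`` no cell is its own
    partner, so pairs always contain two distinct cells.
    """
    k, j = cell
    if not (1 <= k <= K and 1 <= j <= T):
        raise IndexError(f"cell {cell} outside 1..{K} x 1..{T}")
    return (K + 1 - k, T + 1 - j)


@dataclass(frozen=True)
class Design:
    """An immutable stepped wedge design: treatment labels plus observation mask.

    Attributes
    ----------
    X
        ``K x T`` integer array of treatment indicators (0/1). Labels are
        defined for every cell, observed or not.
    observed
        ``K x T`` boolean array; ``True`` where the cluster-period is
        measured.
    """

    X: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=int)
        obs = np.asarray(self.observed, dtype=bool)
        if X.ndim != 2 or X.shape != obs.shape:
            raise StructuralError("X and observed must be equal-shape 2-D arrays")
        X.setflags(write=False)
        obs.setflags(write=False)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "observed", obs)

    @property
    def K(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def pct_removed(self) -> float:
        """Percentage of the K*T cells that are unobserved."""
        return 100.0 * (1.0 - self.n_observed / self.observed.size)

    def is_centrosymmetric(self) -> bool:
        return bool(np.array_equal(self.observed, self.observed[::-1, ::-1]))

    def is_skew_symmetric(self) -> bool:
        """Check X[k,j] = 1 - X[K+1-k, T+1-j] wherever both cells are observed."""
        both = self.observed & self.observed[::-1, ::-1]
        return bool(np.all((self.X + self.X[::-1, ::-1])[both] == 1))

    def observed_periods(self, k: int) -> np.ndarray:
        """0-based sorted indices of periods observed in cluster ``k`` (1-based)."""
        return np.flatnonzero(self.observed[k - 1])

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "K": self.K,
            "X": self.X.tolist(),
            "observed": self.observed.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Design":
        return cls(np.asarray(d["X"]), np.asarray(d["observed"]))

    @classmethod
    def from_json(cls, s: str) -> "Design":
        return cls.from_dict(json.loads(s))

    def schematic(self) -> str:
        """Plain-text schematic: '0'/'1' for observed cells, '.' when unobserved."""
        rows = []
        for k in range(self.K):
            rows.append(
                " ".join(
                    str(self.X[k, j]) if self.observed[k, j] else "."
                    for j in range(self.T)
                )
            )
        return "\n".join(rows)


def build_complete_sw(config: DesignConfig) -> Design:
    """Build the complete standard stepped wedge design for ``config``.

    Row ``k`` (1-based) has ``k`` leading control periods followed by
    ``T - k`` intervention periods; every cell is observed.
    """
    if config.T < 2:
        raise ConfigurationError(f"T must be >= 2, got {config.T}")
    K, T = config.K, config.T
    j = np.arange(1, T + 1)
    k = np.arange(1, K + 1)
    X = (j[None, :] > k[:, None]).astype(int)
    return Design(X, np.ones((K, T), dtype=bool))


def enumerate_pairs(design: Design) -> list[CellPair]:
    """All centrosymmetric pairs whose two cells are both currently observed.

    Each pair appears once, keyed by its lexicographically smaller member,
    and the list is sorted in (cluster, period) order of that member. For a
    complete design this yields ``K*T/2 = T(T-1)/2`` pairs.
    """
    if not design.is_centrosymmetric():
        raise StructuralError("observation mask is not centrosymmetric")
    K, T = design.K, design.T
    pairs = []
    for k in range(1, K + 1):
        for j in range(1, T + 1):
            if not design.observed[k - 1, j - 1]:
                continue
            partner = centrosymmetric_partner((k, j), K, T)
            if (k, j) < partner:
                pairs.append(CellPair((k, j), partner))
    return pairs


def remove_pair(design: Design, pair: CellPair) -> Design:
    """Return a new design with both cells of ``pair`` marked unobserved.

    The input design is left untouched (designs are immutable values), so a
    removal path can retain every intermediate design.
    """
    for k, j in pair.cells():
        if not design.observed[k - 1, j - 1]:
            raise ValueError(f"cell ({k}, {j}) is already unobserved")
    obs = design.observed.copy()
    for k, j in pair.cells():
        obs[k - 1, j - 1] = False
    return Design(design.X, obs)
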