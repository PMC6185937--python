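"""Ranked populations of territorial males on the unit torus.

The hierarchy is a two-class one by default: a fraction phi of the
population is low-ranking with weight ``rho`` relative to the
high-ranking weight, which is normalized to 1 (the dynamics depends
only on weight ratios).  Arbitrary per-individual weights are
supported so multi-rank populations remain constructible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIGH = "HIGH"
LOW = "LOW"

__all__ = ["HIGH", "LOW", "RankedPopulation", "initialize_random", "effective_ratio"]


@dataclass(frozen=True)
class RankedPopulation:
    """Positions, rank labels and weights of all individuals.

    positions : (n, 2) array in [0, 1)^2
    ranks     : (n,) array of labels (HIGH / LOW for the two-class model)
    weights   : (n,) array of positive reals
    """

    positions: np.ndarray
    ranks: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ranks = np.asarray(self.ranks)
        w = np.asarray(self.weights, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(ranks) != len(pos) or len(w) != len(pos):
            raise ValueError("positions, ranks and weights must have equal length")
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def is_low(self) -> np.ndarray:
        return self.ranks == LOW

    @property
    def low_indices(self) -> np.ndarray:
        return np.nonzero(self.is_low)[0]

    @property
    def high_indices(self) -> np.ndarray:
        return np.nonzero(~self.is_low)[0]

    @property
    def phi(self) -> float:
        """Realized fraction of low-ranking individuals."""
        return float(self.is_low.mean())

    def with_positions(self, positions: np.ndarray) -> "RankedPopulation":
        return replace(self, positions=positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "rank": self.ranks,
                "weight": self.weights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RankedPopulation":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x", "y"]].to_numpy(float),
            ranks=df["rank"].to_numpy(),
            weights=df["weight"].to_numpy(float),
        )


def initialize_random(
    n: int,
    phi: float,
    rho: float,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> RankedPopulation:
    """Uniform random population with round(phi * n) low-ranking members.

    Positions are i.i.d. uniform on the unit torus; the low-rank subset
    is chosen uniformly at random.  High-rank weight is 1, low-rank
    weight is ``rho`` in (0, 1].  Reproducible given ``seed``.
    """
    if n < 3:
        raise ValueError("population size must be at least 3")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_low_exact = phi * n
    n_low = int(round(n_low_exact))
    if abs(n_low_exact - n_low) > 1e-9:
        logger.warning("phi * n = %.6g is not an integer; rounding to %d low-rank", n_low_exact, n_low)
    positions = rng.random((n, 2))
    ranks = np.full(n, HIGH, dtype="U4")
    low = rng.choice(n, size=n_low, replace=False)
    ranks[low] = LOW
    weights = np.where(ranks == LOW, rho, 1.0)
    return RankedPopulation(positions=positions, ranks=ranks, weights=weights)


def effective_ratio(pop: RankedPopulation) -> float:
    """rho = (smallest weight) / (largest weight); 1 for a single class."""
    w = pop.weights
    if np.all(pop.is_low) or not np.any(pop.is_low):
        if w.max() != w.min():
            return float(w.min() / w.max())
        logger.warning("single-class population; effective ratio is trivially 1")
        return 1.0
    return float(w.min() / w.max())
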