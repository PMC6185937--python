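"""Per-rank neighbor statistics, the Euler mean-6 law, and class comparison.

For any planar tessellation of the torus whose vertices join exactly
three territories, Euler's relation forces the population mean number
of nearest neighbors to equal 6 regardless of the arrangement of the
points.  With two rank classes this becomes the linear constraint

    (1 - phi) <n_HR> + phi <n_LR> = 6,

so the advantage of high-ranking males — the ratio <n_LR>/<n_HR> — is
a function of <n_HR> and phi alone:

    ratio = 1 + (1 / phi) (6 / <n_HR> - 1).

Per-class degree samples are compared by a two-sided Mann-Whitney
U-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .geometry import NeighborGraph, degree_distribution
from .population import RankedPopulation

logger = logging.getLogger(__name__)

__all__ = ["RankStats", "rank_stats", "euler_residual", "advantage_ratio_from_euler", "compare_classes"]

MEAN_DEGREE = 6.0  # Euler's relation for trivalent planar tessellations


@dataclass(frozen=True)
class RankStats:
    """Neighbor-count distributions and means of a configuration.

    ``dist_*`` map a neighbor count n to the number of individuals
    with that count; means are over individuals.  ``advantage_ratio``
    is mean_LR / mean_HR, the low-rank crowding relative to high rank
    (>= 1 whenever high-ranking males have fewer neighbors).
    """

    dist_hr: dict[int, int]
    dist_lr: dict[int, int]
    dist_all: dict[int, int]
    mean_hr: float
    mean_lr: float
    mean_all: float
    advantage_ratio: float
    degrees_hr: np.ndarray
    degrees_lr: np.ndarray


def rank_stats(pop: RankedPopulation, graph: NeighborGraph) -> RankStats:
    """Per-class and overall neighbor-count statistics of a configuration."""
    if graph.n_points != pop.n:
        raise ValueError("graph and population sizes differ")
    low = pop.low_indices
    high = pop.high_indices
    deg = graph.degrees
    mean_all = float(deg.mean())
    dist_all = degree_distribution(graph)
    if low.size and high.size:
        mean_hr = float(deg[high].mean())
        mean_lr = float(deg[low].mean())
        dist_hr = degree_distribution(graph, high)
        dist_lr = degree_distribution(graph, low)
        ratio = mean_lr / mean_hr
    else:
        # single-class population: per-class fields degenerate to overall
        logger.warning("single-class population; per-class statistics equal overall ones")
        mean_hr = mean_lr = mean_all
        dist_hr = dist_lr = dist_all
        ratio = 1.0
    return RankStats(
        dist_hr=dist_hr,
        dist_lr=dist_lr,
        dist_all=dist_all,
        mean_hr=mean_hr,
        mean_lr=mean_lr,
        mean_all=mean_all,
        advantage_ratio=ratio,
        degrees_hr=deg[high],
        degrees_lr=deg[low],
    )


def euler_residual(stats: RankStats, phi: float) -> float:
    """(1 - phi) <n_HR> + phi <n_LR> - 6; a structural self-test.

    Vanishes (to rounding) on every valid periodic tessellation when
    ``phi`` matches the realized class fractions.
    """
    if stats.degrees_hr.size == 0 or stats.degrees_lr.size == 0:
        raise ValueError("both rank classes must be present")
    return (1.0 - phi) * stats.mean_hr + phi * stats.mean_lr - MEAN_DEGREE


def advantage_ratio_from_euler(mean_hr: float, phi: float) -> float:
    """<n_LR>/<n_HR> implied by the Euler relation: 1 + (1/phi)(6/<n_HR> - 1)."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie strictly between 0 and 1")
    if mean_hr <= 0:
        raise ValueError("mean_hr must be positive")
    return 1.0 + (1.0 / phi) * (MEAN_DEGREE / mean_hr - 1.0)


def compare_classes(degrees_hr: np.ndarray, degrees_lr: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test between per-class degree samples.

    Uses exact enumeration for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Returns (U, p).
    """
    x = np.asarray(degrees_hr, dtype=float)
    y = np.asarray(degrees_lr, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
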