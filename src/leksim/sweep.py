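"""Parameter-grid driver: replicates, convergence bookkeeping, aggregation.

Runs the weighted relaxation over a (phi, rho) grid — by default
0.1 to 1.0 in steps of 0.05, ten replicates per cell — derives one
reproducible seed per (cell, replicate) from the base seed, excludes
non-converged runs from aggregates, and summarizes each cell into
replicate-averaged per-rank neighbor statistics plus pooled degree
distributions for the goodness-of-fit map.  Cells without a single
converged replicate are carried as unavailable (the white regions of
the parameter-space maps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dynamics import ConvergenceReport, DynamicsConfig, run_to_convergence
from .geometry import periodic_neighbor_graph
from .population import RankedPopulation, initialize_random
from .stats import RankStats, compare_classes, rank_stats

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "ReplicateResult",
    "CellSummary",
    "default_grid_values",
    "scaled_config",
    "replicate_seed",
    "run_cell",
    "run_sweep",
    "aggregate",
    "summary_frame",
    "pooled_distributions",
]


def default_grid_values() -> np.ndarray:
    """The canonical grid 0.1, 0.15, ..., 1.0 for both phi and rho."""
    return np.round(np.arange(0.1, 1.0 + 1e-9, 0.05), 6)


def scaled_config() -> DynamicsConfig:
    """Desk-scale profile: relaxed threshold 1e-10, step cap 2e5."""
    return DynamicsConfig(msd_threshold=1e-10, max_steps=200_000)


@dataclass(frozen=True)
class SweepGrid:
    """Grid specification with replicate and seed management."""

    phi_values: np.ndarray = field(default_factory=default_grid_values)
    rho_values: np.ndarray = field(default_factory=default_grid_values)
    replicates: int = 10
    n: int = 400
    base_seed: int = 0
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)

    def __post_init__(self) -> None:
        phis = np.atleast_1d(np.asarray(self.phi_values, dtype=float))
        rhos = np.atleast_1d(np.asarray(self.rho_values, dtype=float))
        if np.any(rhos <= 0) or np.any(rhos > 1):
            raise ValueError("rho values must lie in (0, 1]")
        if np.any(phis < 0) or np.any(phis > 1):
            raise ValueError("phi values must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("at least one replicate per cell")
        object.__setattr__(self, "phi_values", phis)
        object.__setattr__(self, "rho_values", rhos)

    def cells(self) -> Iterable[tuple[float, float]]:
        for phi in self.phi_values:
            for rho in self.rho_values:
                yield float(phi), float(rho)


def replicate_seed(base_seed: int, phi: float, rho: float, replicate: int) -> np.random.SeedSequence:
    """Deterministic, collision-free seed for one (cell, replicate) run.

    The cell coordinates enter as integer counters (grid values are
    multiples of 0.002 in practice), so every (cell, replicate) pair
    maps to a distinct seed stream regardless of the grid layout.
    """
    return np.random.SeedSequence(
        [int(base_seed), int(round(phi * 1000)), int(round(rho * 1000)), int(replicate)]
    )


@dataclass
class ReplicateResult:
    phi: float
    rho: float
    replicate: int
    population: RankedPopulation
    report: ConvergenceReport
    stats: RankStats


@dataclass
class CellSummary:
    """Replicate-averaged statistics of one (phi, rho) cell."""

    phi: float
    rho: float
    n_total: int
    n_converged: int
    mean_hr: float = np.nan
    mean_lr: float = np.nan
    mean_all: float = np.nan
    ratio: float = np.nan
    se_hr: float = np.nan
    se_lr: float = np.nan
    se_ratio: float = np.nan
    mw_u: float = np.nan
    mw_p: float = np.nan
    pooled_dist_hr: dict[int, int] = field(default_factory=dict)
    pooled_dist_lr: dict[int, int] = field(default_factory=dict)
    pooled_dist_all: dict[int, int] = field(default_factory=dict)

    @property
    def available(self) -> bool:
        return self.n_converged > 0


def run_cell(
    phi: float,
    rho: float,
    grid: SweepGrid,
    progress: bool = False,
) -> list[ReplicateResult]:
    """Run all replicates of one parameter cell."""
    out = []
    for rep in range(grid.replicates):
        ss = replicate_seed(grid.base_seed, phi, rho, rep)
        pop = initialize_random(grid.n, phi, rho, rng=np.random.default_rng(ss))
        final, report = run_to_convergence(pop, grid.dynamics)
        graph = periodic_neighbor_graph(final.positions)
        st = rank_stats(final, graph)
        out.append(ReplicateResult(phi, rho, rep, final, report, st))
        if progress:
            logger.info(
                "phi=%.2f rho=%.2f rep=%d: converged=%s steps=%d",
                phi, rho, rep, report.converged, report.steps,
            )
    return out


def run_sweep(grid: SweepGrid, progress: bool = False) -> dict[tuple[float, float], list[ReplicateResult]]:
    """Run every cell of the grid; cells are independent and ordered."""
    results: dict[tuple[float, float], list[ReplicateResult]] = {}
    for phi, rho in grid.cells():
        results[(round(phi, 6), round(rho, 6))] = run_cell(phi, rho, grid, progress=progress)
    return results


def _pool(dists: list[dict[int, int]]) -> dict[int, int]:
    pooled: dict[int, int] = {}
    for d in dists:
        for k, v in d.items():
            pooled[k] = pooled.get(k, 0) + v
    return pooled


def aggregate(replicates: list[ReplicateResult]) -> CellSummary:
    """Collapse one cell's replicates into a summary.

    Non-converged runs are excluded; with zero converged runs the cell
    is returned as unavailable rather than raising.  Means are taken
    over per-replicate means; distributions are pooled by summing
    counts; the Mann-Whitney test compares the pooled per-individual
    degree samples of the two classes.
    """
    if not replicates:
        raise ValueError("no replicates given")
    phi, rho = replicates[0].phi, replicates[0].rho
    conv = [r for r in replicates if r.report.converged]
    summary = CellSummary(phi=phi, rho=rho, n_total=len(replicates), n_converged=len(conv))
    if not conv:
        return summary
    hr = np.array([r.stats.mean_hr for r in conv])
    lr = np.array([r.stats.mean_lr for r in conv])
    al = np.array([r.stats.mean_all for r in conv])
    ratios = np.array([r.stats.advantage_ratio for r in conv])

    def se(a: np.ndarray) -> float:
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else np.nan

    summary.mean_hr = float(hr.mean())
    summary.mean_lr = float(lr.mean())
    summary.mean_all = float(al.mean())
    summary.ratio = float(ratios.mean())
    summary.se_hr = se(hr)
    summary.se_lr = se(lr)
    summary.se_ratio = se(ratios)
    summary.pooled_dist_hr = _pool([r.stats.dist_hr for r in conv])
    summary.pooled_dist_lr = _pool([r.stats.dist_lr for r in conv])
    summary.pooled_dist_all = _pool([r.stats.dist_all for r in conv])
    deg_hr = np.concatenate([r.stats.degrees_hr for r in conv])
    deg_lr = np.concatenate([r.stats.degrees_lr for r in conv])
    if deg_hr.size and deg_lr.size:
        summary.mw_u, summary.mw_p = compare_classes(deg_hr, deg_lr)
    return summary


def summary_frame(results: dict[tuple[float, float], list[ReplicateResult]]) -> pd.DataFrame:
    """Long-format cell summary table (one row per parameter cell)."""
    rows = []
    for (phi, rho), reps in sorted(results.items()):
        s = aggregate(reps)
        rows.append(
            {
                "phi": phi,
                "rho": rho,
                "replicates": s.n_total,
                "converged": s.n_converged,
                "available": s.available,
                "mean_HR": s.mean_hr,
                "mean_LR": s.mean_lr,
                "mean_all": s.mean_all,
                "ratio": s.ratio,
                "se_HR": s.se_hr,
                "se_LR": s.se_lr,
                "U": s.mw_u,
                "p": s.mw_p,
            }
        )
    return pd.DataFrame(rows)


def pooled_distributions(
    results: dict[tuple[float, float], list[ReplicateResult]]
) -> dict[tuple[float, float], dict[int, int] | None]:
    """Per-cell pooled whole-population degree distributions for the gof map.

    Cells with no converged replicate map to ``None`` (unavailable).
    """
    out: dict[tuple[float, float], dict[int, int] | None] = {}
    for key, reps in results.items():
        s = aggregate(reps)
        out[key] = s.pooled_dist_all if s.available else None
    return out


def save_summary(results, path) -> None:
    summary_frame(results).to_csv(path, index=False)


def save_cell_json(summary: CellSummary, path) -> None:
    payload = {
        "phi": summary.phi,
        "rho": summary.rho,
        "replicates": summary.n_total,
        "converged": summary.n_converged,
        "mean_HR": summary.mean_hr,
        "mean_LR": summary.mean_lr,
        "mean_all": summary.mean_all,
        "ratio": summary.ratio,
        "U": summary.mw_u,
        "p": summary.mw_p,
        "dist_HR": {str(k): v for k, v in sorted(summary.pooled_dist_hr.items())},
        "dist_LR": {str(k): v for k, v in sorted(summary.pooled_dist_lr.items())},
        "dist_all": {str(k): v for k, v in sorted(summary.pooled_dist_all.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
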