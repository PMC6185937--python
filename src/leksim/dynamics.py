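"""Rank-weighted territorial relaxation dynamics.

Each time step every individual moves to the midpoint between its
current position and the weighted center of mass of its Voronoi
nearest neighbors,

    x_CM = sum_j w_j x_j / sum_j w_j     (j over neighbors of i),

with neighbor positions unwrapped to their minimum image relative to
the focal individual.  With equal weights this is the classical
Hasegawa--Tanemura centering rule; unequal weights pull individuals
toward high-ranking neighbors.  The update is synchronous: the
neighbor graph and all centers are computed from the configuration at
the start of the step, which makes the dynamics deterministic and
independent of any processing order.

Convergence is declared when the mean squared single-step displacement
(MSD, in squared box-side units) falls below a threshold; runs hitting
the step cap are flagged as non-converged so callers can exclude them
from aggregation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    NeighborGraph,
    _auto_margin,
    _edges_core,
    minimum_image_displacement,
    periodic_edges,
    wrap_position,
)
from .population import RankedPopulation

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicsConfig",
    "ConvergenceReport",
    "weighted_neighbor_center",
    "step",
    "run_to_convergence",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Convergence threshold and step budget.

    msd_threshold : squared box-side units; default 1e-14
    max_steps     : hard cap on iterations; default 4,000,000
    record_interval : if > 0, keep the MSD every that many steps
    """

    msd_threshold: float = 1e-14
    max_steps: int = 4_000_000
    record_interval: int = 0

    def __post_init__(self) -> None:
        if self.msd_threshold <= 0:
            raise ValueError("msd_threshold must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be at least 1")


@dataclass
class ConvergenceReport:
    converged: bool
    steps: int
    final_msd: float
    msd_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "converged": self.converged,
            "steps": self.steps,
            "final_msd": self.final_msd,
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def weighted_neighbor_center(
    focal: int, pop: RankedPopulation, graph: NeighborGraph
) -> np.ndarray:
    """Weighted center of mass of the focal individual's neighbors.

    Neighbors are unwrapped to their minimum image relative to the
    focal position; the result is wrapped back into the unit box.
    """
    nbrs = graph.neighbors(focal)
    if nbrs.size == 0:
        raise RuntimeError(f"individual {focal} has no neighbors; invalid tessellation")
    x0 = pop.positions[focal]
    d = minimum_image_displacement(x0, pop.positions[nbrs])
    w = pop.weights[nbrs]
    return wrap_position(x0 + (w[:, None] * d).sum(axis=0) / w.sum())


def _step_arrays(
    positions: np.ndarray, weights: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, float]:
    """One synchronous update given precomputed edges; returns (moves, msd)."""
    n = len(positions)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    d = positions[j] - positions[i]
    d -= np.floor(d + 0.5)  # minimum image
    wj = weights[j]
    den = np.bincount(i, weights=wj, minlength=n)
    if np.any(den == 0):
        # can only happen when coincident points degenerate the tessellation
        raise RuntimeError("individual with no neighbors; tessellation is degenerate")
    cx = np.bincount(i, weights=wj * d[:, 0], minlength=n)
    cy = np.bincount(i, weights=wj * d[:, 1], minlength=n)
    # displacement of the weighted CM from the focal point is
    # sum_j w_j d_ij / sum_j w_j; the move is half of it (midpoint rule)
    moves = 0.5 * np.stack([cx, cy], axis=1) / den[:, None]
    msd = float(np.einsum("ij,ij->", moves, moves) / n)
    return moves, msd


def step(pop: RankedPopulation, graph: NeighborGraph | None = None) -> tuple[RankedPopulation, float]:
    """Advance the population by one synchronous step.

    Returns the updated population and the mean squared single-step
    displacement.  The tessellation is recomputed from the current
    positions unless a matching ``graph`` is supplied.
    """
    edges = periodic_edges(pop.positions) if graph is None else graph.edges
    moves, msd = _step_arrays(pop.positions, pop.weights, edges)
    return pop.with_positions(wrap_position(pop.positions + moves)), msd


def run_to_convergence(
    pop: RankedPopulation,
    cfg: DynamicsConfig | None = None,
    snapshot_dir=None,
) -> tuple[RankedPopulation, ConvergenceReport]:
    """Iterate the update rule until the MSD drops below threshold.

    Stops either on convergence or at ``cfg.max_steps``; in both cases
    the final configuration and a report are returned, with
    ``report.converged`` marking which applies.  With
    ``cfg.record_interval > 0`` the MSD is traced every that many
    steps and, if ``snapshot_dir`` is given, a population-snapshot CSV
    ``step_<t>.csv`` is written alongside each trace point.
    """
    if cfg is None:
        cfg = DynamicsConfig()
    positions = pop.positions.copy()
    weights = pop.weights
    trace: list[float] = []
    msd = np.inf
    steps_taken = 0
    # the verified tiling margin is sticky across steps (it only grows
    # within a step), but re-tried from the cheap automatic value every
    # few hundred steps so a transient void does not inflate the tiling
    # for the rest of the run
    margin = _auto_margin(len(positions))
    degenerate = False
    for t in range(1, cfg.max_steps + 1):
        if t % 500 == 0:
            margin = _auto_margin(len(positions))
        try:
            edges, margin = _edges_core(positions, margin)
            moves, msd = _step_arrays(positions, weights, edges)
            if not np.all(np.isfinite(moves)):
                degenerate = True
        except Exception:  # qhull breakdown on (near-)coincident points
            degenerate = True
        if degenerate:
            # individuals have merged to identical coordinates and the
            # tessellation no longer exists; the run cannot continue and
            # is reported as non-converged (excluded from aggregates)
            logger.warning(
                "degenerate tessellation (coincident individuals) at step %d; "
                "marking run as non-converged", t,
            )
            msd = float("nan")
            steps_taken = t
            break
        positions += moves
        positions -= np.floor(positions)
        np.subtract(positions, 1.0, out=positions, where=positions >= 1.0)
        steps_taken = t
        if cfg.record_interval and t % cfg.record_interval == 0:
            trace.append(msd)
            if snapshot_dir is not None:
                out = Path(snapshot_dir)
                out.mkdir(parents=True, exist_ok=True)
                pop.with_positions(positions.copy()).to_csv(out / f"step_{t}.csv")
        if msd < cfg.msd_threshold:
            break
    report = ConvergenceReport(
        converged=bool(msd < cfg.msd_threshold),
        steps=steps_taken,
        final_msd=float(msd),
        msd_trace=trace,
        degenerate=degenerate,
    )
    return pop.with_positions(positions), report
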