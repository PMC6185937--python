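"""Synthetic display-site point patterns.

Generators for the point patterns the statistics and goodness-of-fit
pathways consume: complete spatial randomness (CSR), a jittered square
lattice, and model-generated patterns (the converged positions of a
weighted-relaxation run, optionally stripped of rank labels to emulate
field data where individual rank is unknown).  Patterns are written in
the same CSV dialect the observed-pattern reader accepts
(``id,x,y[,label]``) together with a provenance JSON recording the
generating specification and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsConfig, run_to_convergence
from .population import initialize_random

__all__ = [
    "PatternSpec",
    "csr_pattern",
    "perturbed_lattice_pattern",
    "model_pattern",
    "generate_pattern",
    "read_pattern_csv",
    "write_pattern_csv",
]


@dataclass(frozen=True)
class PatternSpec:
    """Specification of a synthetic point pattern.

    kind: "csr", "lattice" or "model"
    n_points: number of display sites (>= 3)
    jitter: uniform jitter half-width in box units (lattice only)
    phi, rho: hierarchy parameters (model only)
    keep_ranks: include rank labels in the output (model only)
    seed: RNG seed
    """

    kind: str
    n_points: int = 106
    jitter: float = 0.05
    phi: float = 0.8
    rho: float = 0.2
    keep_ranks: bool = False
    seed: int = 0
    msd_threshold: float = 1e-10
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "lattice", "model"):
            raise ValueError("kind must be one of csr, lattice, model")
        if self.n_points < 3:
            raise ValueError("at least 3 points")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def csr_pattern(n_points: int, seed: int | None = None) -> np.ndarray:
    """Uniform i.i.d. points on the unit torus (complete spatial randomness)."""
    rng = np.random.default_rng(seed)
    return rng.random((n_points, 2))


def perturbed_lattice_pattern(n_points: int, jitter: float, seed: int | None = None) -> np.ndarray:
    """Square lattice of ~n_points sites plus seeded uniform jitter.

    The lattice side is ceil(sqrt(n_points)); surplus sites are
    dropped at random so exactly ``n_points`` remain.  Duplicate
    points (possible only at jitter = 0 after dropping) trigger a
    logged reseed.
    """
    rng = np.random.default_rng(seed)
    k = int(np.ceil(np.sqrt(n_points)))
    xs = (np.arange(k) + 0.5) / k
    gx, gy = np.meshgrid(xs, xs)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    keep = rng.choice(len(pts), size=n_points, replace=False)
    pts = pts[np.sort(keep)]
    for _ in range(100):
        out = pts + rng.uniform(-jitter, jitter, size=pts.shape)
        out -= np.floor(out)
        if len(np.unique(out, axis=0)) == len(out):
            return out
    raise RuntimeError("could not generate a duplicate-free pattern")


def model_pattern(
    n_points: int,
    phi: float,
    rho: float,
    seed: int | None = None,
    msd_threshold: float = 1e-10,
    max_steps: int = 200_000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Converged positions of a weighted-relaxation run.

    Returns (positions, rank labels, converged flag).  The same seed
    reproduces the same simulation exactly.
    """
    pop = initialize_random(n_points, phi, rho, seed=seed)
    final, report = run_to_convergence(
        pop, DynamicsConfig(msd_threshold=msd_threshold, max_steps=max_steps)
    )
    return final.positions, final.ranks, report.converged


def generate_pattern(spec: PatternSpec, out_csv=None, out_json=None) -> pd.DataFrame:
    """Generate a pattern per spec; optionally write CSV + provenance JSON."""
    labels = None
    converged = None
    if spec.kind == "csr":
        pts = csr_pattern(spec.n_points, seed=spec.seed)
    elif spec.kind == "lattice":
        pts = perturbed_lattice_pattern(spec.n_points, spec.jitter, seed=spec.seed)
    else:
        pts, ranks, converged = model_pattern(
            spec.n_points, spec.phi, spec.rho, seed=spec.seed,
            msd_threshold=spec.msd_threshold, max_steps=spec.max_steps,
        )
        if spec.keep_ranks:
            labels = ranks
    df = pd.DataFrame({"id": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1]})
    if labels is not None:
        df["label"] = labels
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_json is not None:
        prov = asdict(spec)
        if converged is not None:
            prov["converged"] = converged
        Path(out_json).write_text(json.dumps(prov, indent=2))
    return df


def write_pattern_csv(points: np.ndarray, path, labels=None) -> None:
    df = pd.DataFrame({"id": np.arange(len(points)), "x": points[:, 0], "y": points[:, 1]})
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)


def read_pattern_csv(path, rescale: bool = False) -> tuple[np.ndarray, pd.DataFrame]:
    """Read an ``id,x,y[,label/tag]`` pattern table.

    With ``rescale=True`` an arbitrary rectangular window is mapped
    onto the unit square (each axis scaled by the common factor that
    fits the longer side, so relative geometry is preserved); the
    applied offsets and factor are attached to the returned frame's
    ``attrs``.  Tags such as tagged/untagged/undetermined are accepted
    and ignored by all computations.
    """
    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(float)
    if rescale:
        lo = pts.min(axis=0)
        span = pts.max(axis=0) - lo
        scale = float(span.max()) or 1.0
        pts = (pts - lo) / scale
        # strictly inside [0, 1): nudge points on the far edge
        pts = np.clip(pts, 0.0, np.nextafter(1.0, 0.0))
        df.attrs["rescale_offset"] = lo.tolist()
        df.attrs["rescale_factor"] = scale
    if np.any(pts < 0) or np.any(pts >= 1):
        raise ValueError("pattern coordinates outside [0, 1); pass rescale=True")
    return pts, df
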