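"""Independent brute-force oracles used to validate the implementation.

Deliberately slow and simple: the periodic Voronoi adjacency oracle
builds every cell by clipping a large polygon against the
perpendicular-bisector half-planes of all periodic images of all
other points, then reads adjacency off positive-length shared
boundary segments.  The Mann-Whitney oracle estimates the two-sided
p-value by random permutation of the pooled sample.
"""

from __future__ import annotations

import itertools

import numpy as np

_OFFSETS = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=2)))


def _clip_halfplane(poly: list[np.ndarray], n: np.ndarray, c: float) -> list[np.ndarray]:
    """Sutherland-Hodgman clip of polygon to {x : n . x <= c}."""
    out: list[np.ndarray] = []
    k = len(poly)
    for idx in range(k):
        a, b = poly[idx], poly[(idx + 1) % k]
        fa, fb = float(n @ a - c), float(n @ b - c)
        inside_a, inside_b = fa <= 0.0, fb <= 0.0
        if inside_a:
            out.append(a)
        if inside_a != inside_b:
            t = fa / (fa - fb)
            out.append(a + t * (b - a))
    return out


def brute_force_periodic_adjacency(points: np.ndarray, tol: float = 1e-9) -> set[tuple[int, int]]:
    """Exact periodic Voronoi adjacency by half-plane intersection."""
    points = np.asarray(points, dtype=float)
    npts = len(points)
    adj: set[tuple[int, int]] = set()
    for i in range(npts):
        p = points[i]
        # start from a box comfortably containing the cell
        poly = [p + np.array(v) for v in ((-1.4, -1.4), (1.4, -1.4), (1.4, 1.4), (-1.4, 1.4))]
        cutters: list[tuple[int, np.ndarray, float]] = []
        for j in range(npts):
            for off in _OFFSETS:
                g = points[j] + off
                if j == i and np.all(off == 0):
                    continue
                n = g - p
                c = float(n @ (p + g) / 2.0)
                cutters.append((j, n, c))
                poly = _clip_halfplane(poly, n, c)
                if not poly:
                    raise RuntimeError("cell clipped away; degenerate input")
        verts = np.array(poly)
        k = len(verts)
        for j, n, c in cutters:
            if j == i:
                continue
            # boundary length of the cell lying on this bisector line
            length = 0.0
            for idx in range(k):
                a, b = verts[idx], verts[(idx + 1) % k]
                if abs(n @ a - c) < tol * max(1.0, np.linalg.norm(n)) and abs(
                    n @ b - c
                ) < tol * max(1.0, np.linalg.norm(n)):
                    length += float(np.linalg.norm(b - a))
            if length > 1e-9:
                adj.add((min(i, j), max(i, j)))
    return adj


def permutation_mannwhitney(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided Mann-Whitney p-value by Monte-Carlo permutation.

    The U statistic (for the first sample, with the tie convention
    counting half for equal pairs) is recomputed under random
    relabelings of the pooled observations; the p-value is the
    fraction of permutations at least as far from the null mean
    n1*n2/2 as the observed statistic (add-one corrected).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_stat(a: np.ndarray, b: np.ndarray) -> float:
        diff = a[:, None] - b[None, :]
        return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))

    mu = n1 * n2 / 2.0
    observed = abs(u_stat(x, y) - mu)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(u_stat(perm[:n1], perm[n1:]) - mu) >= observed - 1e-12:
            hits += 1
    return u_stat(x, y), (hits + 1) / (n_perm + 1)
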