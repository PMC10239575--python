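"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the Delaunay oracle
enumerates point triples/quadruples and tests empty circumcircles/spheres
directly, and the threshold oracle evaluates the efficiency statistic on a
dense grid by direct counting.
"""

from __future__ import annotations

import itertools

import numpy as np


def _circumcenter(points: np.ndarray):
    """Circumcenter of d+1 points in d dimensions, or None if degenerate."""
    p0 = points[0]
    A = 2.0 * (points[1:] - p0)
    b = np.sum(points[1:] ** 2, axis=1) - np.sum(p0**2)
    try:
        center = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    return center


def brute_force_delaunay_edges(coords: np.ndarray) -> set:
    """Delaunay edge set by exhaustive empty-circumcircle/-sphere testing.

    Assumes general position (no cocircular/cospherical subsets), which holds
    with probability 1 for continuous random coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    n, dim = coords.shape
    edges = set()
    for simplex in itertools.combinations(range(n), dim + 1):
        pts = coords[list(simplex)]
        center = _circumcenter(pts)
        if center is None:
            continue
        r2 = float(np.sum((pts[0] - center) ** 2))
        others = [k for k in range(n) if k not in simplex]
        d2 = np.sum((coords[others] - center) ** 2, axis=1)
        if np.all(d2 > r2 * (1 + 1e-12)):
            edges.update(itertools.combinations(simplex, 2))
    return {tuple(sorted(e)) for e in edges}


def brute_force_best_thresholds(r: np.ndarray, theta: np.ndarray, grid: int = 500):
    """Best efficiency over a dense rectangular grid, by direct counting."""
    r = np.asarray(r, float)
    theta = np.asarray(theta, float)
    m = len(r)
    rs = np.linspace(r.min(), r.max(), grid)
    ts = np.linspace(theta.min(), theta.max(), grid)
    r_mask = r[:, None] <= rs[None, :]          # m x grid
    t_mask = theta[:, None] <= ts[None, :]      # m x grid
    F = (r_mask.astype(float).T @ t_mask.astype(float)) / m  # grid x grid counts
    lr = np.zeros(grid) if r.max() == r.min() else (rs - r.min()) / (r.max() - r.min())
    lt = (
        np.zeros(grid)
        if theta.max() == theta.min()
        else (ts - theta.min()) / (theta.max() - theta.min())
    )
    E = F - 0.5 * (lr[:, None] + lt[None, :])
    k = np.argwhere(E == E.max())[0]
    return float(E[k[0], k[1]]), float(rs[k[0]]), float(ts[k[1]])
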