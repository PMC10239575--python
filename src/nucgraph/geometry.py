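"""Candidate neighbor graphs from nuclei centroids.

The cell-cell contact graph is approximated by the Delaunay triangulation of
the nuclei centroids: the triangulation is the dual of the Voronoi diagram,
so for space-filling convex cells every true membrane contact corresponds to
a Delaunay edge (and the triangulation always contains the nearest-neighbor
graph).  In 3D the Delaunay cells are tetrahedra; each tetrahedron is
decomposed into its four triangular faces so that the downstream angle
statistic is defined identically in both dimensions.

Each candidate edge (i, j) is annotated with two geometric features:

* ``r_ij`` — the Euclidean distance between the two centroids (a pairwise
  quantity), and
* ``theta_ij`` — the maximum angle, in degrees, subtended by i and j at any
  shared triangulation neighbor k (the angle i-k-j).  This is a non-pairwise
  quantity: it approaches 180 degrees when a third cell k sits between i and
  j and blocks their contact, and is small when i and j are isolated from
  the rest of the tissue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

__all__ = [
    "CentroidSet",
    "CandidateGraph",
    "EdgeFeatureTable",
    "GeometryError",
    "DegenerateInputError",
    "DuplicatePointError",
    "TooFewPointsError",
    "build_candidate_graph",
    "compute_edge_features",
]

# Points closer than this fraction of the bounding-box diagonal are treated
# as duplicates (an upstream segmentation fault) and rejected.
DUPLICATE_TOLERANCE = 1e-9


class GeometryError(ValueError):
    """Base class for invalid centroid configurations."""


class TooFewPointsError(GeometryError):
    pass


class DegenerateInputError(GeometryError):
    """All points collinear (2D) / coplanar (3D): no triangulation exists."""


class DuplicatePointError(GeometryError):
    pass


@dataclass(frozen=True)
class CentroidSet:
    """A labelled point cloud of nuclei centroids in 2 or 3 dimensions.

    Parameters
    ----------
    ids
        Unique integer labels, one per nucleus.
    coords
        Array of shape ``(n, dim)`` with ``dim`` in {2, 3}, in arbitrary but
        consistent physical length units.  Anisotropic voxel sizes must be
        applied *before* constructing the set: the angle feature is invariant
        under similarity transforms but not under anisotropic scaling.
    """

    ids: tuple
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "ids", tuple(int(i) for i in self.ids))
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise GeometryError(
                f"coords must have shape (n, 2) or (n, 3), got {coords.shape}"
            )
        if len(self.ids) != coords.shape[0]:
            raise GeometryError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise GeometryError("centroid ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        self._check_duplicates(coords)

    @staticmethod
    def _check_duplicates(coords: np.ndarray) -> None:
        if len(coords) < 2:
            return
        span = coords.max(axis=0) - coords.min(axis=0)
        diag = float(np.linalg.norm(span))
        tol = DUPLICATE_TOLERANCE * diag if diag > 0 else 0.0
        pairs = cKDTree(coords).query_pairs(r=tol)
        if diag == 0 or pairs:
            raise DuplicatePointError(
                "duplicate (or near-duplicate) centroids detected; "
                "check the upstream segmentation"
            )

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def coords_by_id(self) -> dict:
        return {i: self.coords[k] for k, i in enumerate(self.ids)}

    def transformed(self, matrix=None, scale=1.0, offset=0.0) -> "CentroidSet":
        """Return a copy with coordinates mapped through ``scale * (x @ M.T) + offset``."""
        pts = self.coords
        if matrix is not None:
            pts = pts @ np.asarray(matrix, dtype=float).T
        pts = scale * pts + offset
        return CentroidSet(self.ids, pts)


@dataclass(frozen=True)
class CandidateGraph:
    """Delaunay edge and triangle sets over centroid ids.

    ``triangles`` holds the 2D Delaunay triangles, or in 3D the union of the
    four triangular faces of every tetrahedron (faces shared between two
    tetrahedra appear once).  Every edge lies in at least one triangle.
    """

    nodes: tuple
    edges: frozenset  # of sorted (i, j) tuples
    triangles: frozenset  # of sorted (i, j, k) tuples

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def triangles_of_edge(self) -> dict:
        """Map each edge to the ids of the opposite vertices of its triangles."""
        opposite: dict = {e: [] for e in self.edges}
        for tri in self.triangles:
            for a, b in itertools.combinations(tri, 2):
                k = next(v for v in tri if v != a and v != b)
                opposite[(a, b)].append(k)
        return opposite


@dataclass
class EdgeFeatureTable:
    """Per-edge features of a candidate graph: distance and max subtended angle."""

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray       # length units, > 0
    theta: np.ndarray   # degrees, in (0, 180]

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.r) == len(self.theta)):
            raise ValueError("feature columns must have equal length")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def r_min(self) -> float:
        return float(self.r.min())

    @property
    def r_max(self) -> float:
        return float(self.r.max())

    @property
    def theta_min(self) -> float:
        return float(self.theta.min())

    @property
    def theta_max(self) -> float:
        return float(self.theta.max())

    def edges(self) -> list:
        return [tuple(sorted((a, b))) for a, b in zip(self.i, self.j)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"i": self.i, "j": self.j, "r": self.r, "theta": self.theta}
        )


def build_candidate_graph(centroids: CentroidSet) -> CandidateGraph:
    """Delaunay-triangulate the centroids and return edges and triangles.

    In 3D, tetrahedra are decomposed into their four triangular faces before
    edge extraction.  Raises :class:`TooFewPointsError` for fewer than dim+1
    points and :class:`DegenerateInputError` for collinear/coplanar input.
    """
    coords = centroids.coords
    dim = centroids.dim
    if len(coords) < dim + 1:
        raise TooFewPointsError(
            f"need at least {dim + 1} points in {dim}D, got {len(coords)}"
        )
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise DegenerateInputError(
            f"degenerate point configuration in {dim}D "
            "(collinear or coplanar input?)"
        ) from exc
    if tri.simplices.size == 0 or tri.simplices.shape[1] != dim + 1:
        raise DegenerateInputError("triangulation produced no full-dimensional simplices")

    ids = np.asarray(centroids.ids)
    triangles = set()
    for simplex in ids[tri.simplices]:
        if dim == 2:
            triangles.add(tuple(sorted(int(v) for v in simplex)))
        else:
            # tetrahedron -> its 4 triangular faces
            for face in itertools.combinations(simplex, 3):
                triangles.add(tuple(sorted(int(v) for v in face)))

    edges = set()
    for t in triangles:
        edges.update(itertools.combinations(t, 2))
    return CandidateGraph(
        nodes=centroids.ids,
        edges=frozenset(edges),
        triangles=frozenset(triangles),
    )


def _angle_deg(k: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle at vertex k between rays k->a and k->b, in degrees."""
    u = a - k
    v = b - k
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("degenerate angle: coincident points")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_edge_features(
    graph: CandidateGraph, centroids: CentroidSet
) -> EdgeFeatureTable:
    """Annotate every candidate edge with (r_ij, theta_ij).

    ``theta_ij`` is maximized over the opposite vertices of the triangles
    containing the edge, i.e. over the shared triangulation neighbors of i
    and j.
    """
    pos = centroids.coords_by_id()
    missing = [v for t in graph.triangles for v in t if v not in pos]
    if missing:
        raise GeometryError(f"triangle ids not present in centroid set: {missing[:5]}")
    opposite = graph.triangles_of_edge()
    ii, jj, rr, tt = [], [], [], []
    for (a, b) in sorted(graph.edges):
        ks = opposite[(a, b)]
        if not ks:
            raise GeometryError(f"edge {(a, b)} belongs to no triangle")
        pa, pb = pos[a], pos[b]
        ii.append(a)
        jj.append(b)
        rr.append(float(np.linalg.norm(pa - pb)))
        tt.append(max(_angle_deg(pos[k], pa, pb) for k in ks))
    return EdgeFeatureTable(np.array(ii), np.array(jj), np.array(rr), np.array(tt))
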