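"""End-to-end inference: centroids -> filtered neighbor graph."""

from __future__ import annotations

from typing import Optional, Tuple

from .filtering import (
    EfficiencySurface,
    NeighborGraph,
    Thresholds,
    filter_edges,
    optimize_distance_only,
    optimize_thresholds,
)
from .geometry import CentroidSet, build_candidate_graph, compute_edge_features

__all__ = ["infer_neighbor_graph"]


def infer_neighbor_graph(
    centroids: CentroidSet, mode: str = "joint"
) -> Tuple[NeighborGraph, Thresholds, Optional[EfficiencySurface]]:
    """Run the full method on a centroid set.

    Builds the Delaunay candidate graph, computes per-edge (r, theta)
    features, selects thresholds by maximizing the communicability
    efficiency (jointly over distance and angle, or over distance alone when
    ``mode="distance_only"``), and filters the candidate edges.

    Returns the filtered graph, the selected thresholds, and — in joint
    mode — the efficiency surface over the observed feature grid.
    """
    if mode not in ("joint", "distance_only"):
        raise ValueError(f"mode must be 'joint' or 'distance_only', got {mode!r}")
    graph = build_candidate_graph(centroids)
    features = compute_edge_features(graph, centroids)
    if mode == "joint":
        thresholds, surface = optimize_thresholds(features)
    else:
        thresholds = optimize_distance_only(features)
        surface = None
    return filter_edges(graph, features, thresholds), thresholds, surface
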