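"""Automatic threshold selection by communicability efficiency.

A candidate edge (i, j) is accepted as a true cell-cell contact iff

    r_ij <= r*   and   theta_ij <= Theta*,

where the critical pair (r*, Theta*) is chosen, with no free parameters, by
maximizing the communicability efficiency of the resulting graph

    E(r, Theta) = F(r, Theta) - L(r, Theta).

F is the joint empirical CDF of the observed edge features — the fraction of
candidate edges with r_ij <= r and theta_ij <= Theta — i.e. the fraction of
pairs that stay connected at those thresholds.  L is the connectivity loss
that the same thresholds would incur if the features were uniformly
distributed over their observed ranges; here the mean of the two min-max
normalized coordinates:

    L_mean(r, Theta) = 1/2 * ( (r - r_min)/(r_max - r_min)
                             + (Theta - Theta_min)/(Theta_max - Theta_min) ).

E weighs the edges actually retained against the edges a featureless random
tissue would retain: at the joint minima L = 0 but almost nothing is
connected; at the joint maxima F = 1 but L = 1, so E = 0.  Real tissues
concentrate their edge features well below the extremes, so E has an
interior maximum that separates true contacts from the long, obstructed
links the triangulation adds along the hull and across gaps.

A distance-only variant (E(r) = F(r) - L(r) with the same min-max loss in r)
serves as the pairwise-interaction baseline for ablation: it cannot remove a
short edge that is blocked by an intervening cell, which only the angle term
detects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import CandidateGraph, EdgeFeatureTable

__all__ = [
    "EfficiencySurface",
    "Thresholds",
    "NeighborGraph",
    "ecdf_fraction",
    "loss_mean",
    "efficiency",
    "optimize_thresholds",
    "optimize_distance_only",
    "filter_edges",
]


@dataclass(frozen=True)
class EfficiencySurface:
    """E = F - L evaluated on the grid of observed unique feature values."""

    r_values: np.ndarray        # sorted unique observed r_ij
    theta_values: np.ndarray    # sorted unique observed theta_ij
    F: np.ndarray               # (len(r), len(theta)) joint ECDF
    L: np.ndarray               # (len(r), len(theta)) loss
    E: np.ndarray               # F - L

    def to_dataframe(self):
        """Long-format table (r, theta, F, L, E), one row per grid point."""
        import pandas as pd

        rr, tt = np.meshgrid(self.r_values, self.theta_values, indexing="ij")
        return pd.DataFrame(
            {
                "r": rr.ravel(),
                "theta": tt.ravel(),
                "F": self.F.ravel(),
                "L": self.L.ravel(),
                "E": self.E.ravel(),
            }
        )


@dataclass(frozen=True)
class Thresholds:
    """The selected critical pair (r*, Theta*)."""

    r_star: float
    theta_star: float
    efficiency_at_optimum: float
    mode: str = "joint"  # "joint" | "distance_only"


@dataclass(frozen=True)
class NeighborGraph:
    """The filtered graph: candidate edges with a kept/removed flag."""

    nodes: tuple
    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    kept: np.ndarray  # bool per candidate edge

    @property
    def kept_edges(self) -> set:
        return {
            tuple(sorted((int(a), int(b))))
            for a, b, k in zip(self.i, self.j, self.kept)
            if k
        }

    @property
    def n_candidate_edges(self) -> int:
        return len(self.kept)

    @property
    def fraction_removed(self) -> float:
        if len(self.kept) == 0:
            return 0.0
        return 1.0 - float(self.kept.sum()) / len(self.kept)

    def to_networkx(self):
        """Kept edges as a networkx Graph with r/theta edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(n) for n in self.nodes)
        for a, b, r, t, k in zip(self.i, self.j, self.r, self.theta, self.kept):
            if k:
                g.add_edge(int(a), int(b), r=float(r), theta=float(t))
        return g


def ecdf_fraction(features: EdgeFeatureTable, r: float, theta: float) -> float:
    """Fraction of candidate edges with r_ij <= r and theta_ij <= theta."""
    if len(features) == 0:
        raise ValueError("empty feature table")
    ok = (features.r <= r) & (features.theta <= theta)
    return float(ok.mean())


def _norm(x: float, lo: float, hi: float) -> float:
    # A collapsed axis (hi == lo) cannot filter anything: its loss term is 0.
    if hi == lo:
        return 0.0
    return (x - lo) / (hi - lo)


def loss_mean(r: float, theta: float, features: EdgeFeatureTable) -> float:
    """Mean of the min-max-normalized coordinates over the observed ranges."""
    if len(features) == 0:
        raise ValueError("empty feature table")
    if not (features.r_min <= r <= features.r_max):
        raise ValueError(f"r={r} outside observed range [{features.r_min}, {features.r_max}]")
    if not (features.theta_min <= theta <= features.theta_max):
        raise ValueError(
            f"theta={theta} outside observed range "
            f"[{features.theta_min}, {features.theta_max}]"
        )
    return 0.5 * (
        _norm(r, features.r_min, features.r_max)
        + _norm(theta, features.theta_min, features.theta_max)
    )


def efficiency(r: float, theta: float, features: EdgeFeatureTable) -> float:
    """Communicability efficiency E(r, Theta) = F(r, Theta) - L_mean(r, Theta)."""
    return ecdf_fraction(features, r, theta) - loss_mean(r, theta, features)


def _joint_ecdf_grid(features: EdgeFeatureTable, ru: np.ndarray, tu: np.ndarray) -> np.ndarray:
    """Joint ECDF on the ru x tu grid via a 2D cumulative count."""
    m = len(features)
    ri = np.searchsorted(ru, features.r)
    ti = np.searchsorted(tu, features.theta)
    counts = np.zeros((len(ru), len(tu)))
    np.add.at(counts, (ri, ti), 1.0)
    return counts.cumsum(axis=0).cumsum(axis=1) / m


def optimize_thresholds(features: EdgeFeatureTable):
    """Maximize E over the grid of observed unique (r, Theta) values.

    F is piecewise constant with jumps only at observed feature values while
    L strictly increases between them, so the continuous-domain maximum is
    attained on this grid.  Ties are broken toward smaller r, then smaller
    Theta (the stricter graph).

    Returns
    -------
    (Thresholds, EfficiencySurface)
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    ru = np.unique(features.r)
    tu = np.unique(features.theta)
    F = _joint_ecdf_grid(features, ru, tu)
    Lr = _norm_arr(ru, features.r_min, features.r_max)
    Lt = _norm_arr(tu, features.theta_min, features.theta_max)
    L = 0.5 * (Lr[:, None] + Lt[None, :])
    E = F - L
    best = np.argwhere(E == E.max())[0]  # argwhere is lexicographic: min r, then min theta
    thr = Thresholds(
        r_star=float(ru[best[0]]),
        theta_star=float(tu[best[1]]),
        efficiency_at_optimum=float(E[best[0], best[1]]),
        mode="joint",
    )
    return thr, EfficiencySurface(ru, tu, F, L, E)


def _norm_arr(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def optimize_distance_only(features: EdgeFeatureTable) -> Thresholds:
    """Distance-only baseline: maximize E(r) = F(r) - L(r) over unique r.

    The angle is left unconstrained (theta* = observed theta_max), so the
    filter reduces to a pure pairwise distance threshold.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    ru = np.unique(features.r)
    F = np.searchsorted(np.sort(features.r), ru, side="right") / len(features)
    L = _norm_arr(ru, features.r_min, features.r_max)
    E = F - L
    best = int(np.argmax(E))  # argmax returns the first (smallest-r) maximizer
    return Thresholds(
        r_star=float(ru[best]),
        theta_star=features.theta_max,
        efficiency_at_optimum=float(E[best]),
        mode="distance_only",
    )


def filter_edges(
    graph: CandidateGraph,
    features: EdgeFeatureTable,
    thresholds: Thresholds,
) -> NeighborGraph:
    """Keep the candidate edges with r_ij <= r* and theta_ij <= Theta*."""
    kept = (features.r <= thresholds.r_star) & (features.theta <= thresholds.theta_star)
    return NeighborGraph(
        nodes=graph.nodes,
        i=features.i.copy(),
        j=features.j.copy(),
        r=features.r.copy(),
        theta=features.theta.copy(),
        kept=kept,
    )
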