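"""File I/O: centroid tables, edge lists, image front-end, run outputs.

Centroid tables are comma-separated UTF-8 with a mandatory header and
columns ``id,x,y[,z]``; coordinates are physical (index times voxel spacing
when extracted from an image).  The presence of a ``z`` column makes the set
3D unless the caller forces 2D.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import MetricsReport
from .filtering import NeighborGraph, Thresholds
from .geometry import CentroidSet

__all__ = [
    "read_centroids",
    "write_centroids",
    "read_edge_list",
    "write_edge_list",
    "read_image",
    "extract_centroids",
    "write_outputs",
]

logger = logging.getLogger("nucgraph")

_FLOAT_FMT = "%.15g"  # >= 12 significant digits so write/read round-trips


def read_centroids(path, force_2d: bool = False) -> CentroidSet:
    """Read a centroid CSV with columns id,x,y[,z]."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"centroid table must have columns id,x,y[,z]; got {list(df.columns)}")
    cols = ["x", "y"]
    if "z" in df.columns and not force_2d:
        cols.append("z")
    for c in ["id"] + cols:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"non-numeric values in column {c!r}")
    ids = df["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate centroid ids in table")
    return CentroidSet(tuple(int(i) for i in ids), df[cols].to_numpy(dtype=float))


def write_centroids(path, centroids: CentroidSet) -> None:
    cols = ["x", "y", "z"][: centroids.dim]
    df = pd.DataFrame(centroids.coords, columns=cols)
    df.insert(0, "id", centroids.ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_edge_list(path) -> set:
    """Read an edge CSV with columns i,j (extra columns ignored)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"i", "j"}.issubset(df.columns):
        raise ValueError("edge list must have columns i,j")
    return {
        tuple(sorted((int(a), int(b))))
        for a, b in zip(df["i"], df["j"])
    }


def write_edge_list(path, edges) -> None:
    rows = sorted(tuple(sorted(map(int, e))) for e in edges)
    pd.DataFrame(rows, columns=["i", "j"]).to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path))


def write_image(path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def extract_centroids(
    image: np.ndarray,
    spacing=None,
    min_size: int = 4,
) -> CentroidSet:
    """Detect nuclei centroids in a single-channel 2D/3D image.

    Foreground is selected by Otsu's global threshold and cleaned by a
    morphological opening with a 3^d structuring element (pure-noise speckle
    percolates at the Otsu threshold, so a size filter alone cannot reject
    it; opening suppresses it while leaving blob-shaped nuclei intact).  The
    mask is labelled by connected components (8-connectivity in 2D,
    26-connectivity in 3D), components below ``min_size`` voxels are
    discarded, and each centroid is the intensity-weighted center of mass in
    physical units (voxel index times per-axis ``spacing``).  Nuclei are
    assumed to span at least ~3 voxels per axis.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D single-channel image, got ndim={image.ndim}")
    spacing = np.ones(image.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    if spacing.shape != (image.ndim,) or np.any(spacing <= 0):
        raise ValueError("spacing must be one positive value per image axis")
    if np.ptp(image) == 0:
        raise ValueError("image is constant: no foreground after thresholding")
    mask = image > threshold_otsu(image)
    mask = ndimage.binary_opening(mask, structure=np.ones((3,) * image.ndim))
    if not mask.any():
        raise ValueError("empty foreground after thresholding and denoising")
    labels = label(mask, connectivity=image.ndim)  # full connectivity: 8 / 26
    index = np.arange(1, labels.max() + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index)
    keep = index[sizes >= min_size]
    if len(keep) == 0:
        raise ValueError(f"no components of at least {min_size} voxels")
    weighted = np.clip(image, 0, None)
    centers = ndimage.center_of_mass(weighted, labels, keep)
    coords = np.asarray(centers, dtype=float) * spacing
    logger.info("extracted %d centroids from image of shape %s", len(coords), image.shape)
    return CentroidSet(tuple(range(len(coords))), coords)


def write_outputs(
    graph: NeighborGraph,
    thresholds: Thresholds,
    outdir,
    metrics: Optional[MetricsReport] = None,
    seed: Optional[int] = None,
    graphml: bool = True,
) -> dict:
    """Write the standard result files to ``outdir``; returns their paths.

    Files: ``edges.csv`` (i,j,r,theta,kept for every candidate edge),
    ``summary.json`` (selected thresholds and run statistics),
    ``metrics.json`` if ground truth was supplied, and ``graph.graphml``
    with the kept edges.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    edges = pd.DataFrame(
        {
            "i": graph.i,
            "j": graph.j,
            "r": graph.r,
            "theta": graph.theta,
            "kept": graph.kept,
        }
    )
    paths["edges"] = outdir / "edges.csv"
    edges.to_csv(paths["edges"], index=False, float_format=_FLOAT_FMT)

    summary = {
        "r_star": thresholds.r_star,
        "theta_star": thresholds.theta_star,
        "efficiency_at_optimum": thresholds.efficiency_at_optimum,
        "mode": thresholds.mode,
        "n_nodes": len(graph.nodes),
        "n_candidate_edges": graph.n_candidate_edges,
        "n_kept_edges": int(graph.kept.sum()),
        "fraction_removed": graph.fraction_removed,
        "seed": seed,
        "ground_truth": metrics is not None,
        "version": __version__,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    if metrics is not None:
        paths["metrics"] = outdir / "metrics.json"
        paths["metrics"].write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n")

    if graphml:
        import networkx as nx

        paths["graphml"] = outdir / "graph.graphml"
        nx.write_graphml(graph.to_networkx(), paths["graphml"])

    logger.info(
        "thresholds r*=%.6g theta*=%.4g deg; removed %.1f%% of %d candidate links",
        thresholds.r_star,
        thresholds.theta_star,
        100 * graph.fraction_removed,
        graph.n_candidate_edges,
    )
    return paths
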