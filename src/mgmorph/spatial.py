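"""Population-level spatial statistics of cell and nucleus centroids.

Delaunay-based neighbor measures follow the common cytometry convention:
triangulate once, then discard edges longer than a distance cutoff (the graph
is not re-triangulated).  Degenerate inputs (collinear points, < 3 points
where a triangulation is undefined but a neighbor notion still makes sense)
fall back to the complete all-pairs graph under the same cutoff, with a log
entry.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core import RegionAnnotation

logger = logging.getLogger(__name__)


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Deterministically perturb exact duplicates by < 1e-6 μm."""
    points = points.astype(float).copy()
    seen: Dict[Tuple[float, float], int] = {}
    for i, p in enumerate(map(tuple, points)):
        k = seen.get(p, 0)
        if k:
            points[i] += (k * 1e-7, k * 1.5e-7)
            logger.warning("duplicate point at %s perturbed deterministically", p)
        seen[p] = k + 1
    return points


def _delaunay_edges(points: np.ndarray) -> Set[Tuple[int, int]]:
    tri = Delaunay(points)
    edges: Set[Tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def _all_pairs_edges(n: int) -> Set[Tuple[int, int]]:
    return {(i, j) for i in range(n) for j in range(i + 1, n)}


def _neighbor_graph(points: np.ndarray) -> Set[Tuple[int, int]]:
    """Delaunay edge set, or the all-pairs graph for degenerate inputs."""
    n = len(points)
    if n < 3:
        return _all_pairs_edges(n)
    try:
        return _delaunay_edges(_dedupe(points))
    except QhullError:
        logger.warning("degenerate point set; falling back to all-pairs graph")
        return _all_pairs_edges(n)


def delaunay_mean_neighbor_distance(
    points_um: np.ndarray, max_distance_um: float = 250.0
) -> np.ndarray:
    """Per-point mean length of incident Delaunay edges <= the cutoff.

    Points with no remaining edges — and every point when fewer than 3 points
    are supplied — get NaN.
    """
    points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
    n = len(points_um)
    out = np.full(n, np.nan)
    if n < 3:
        return out
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for i, j in _neighbor_graph(points_um):
        d = float(np.hypot(*(points_um[i] - points_um[j])))
        if d > max_distance_um:
            continue
        sums[i] += d
        sums[j] += d
        counts[i] += 1
        counts[j] += 1
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def clump_neighbors(
    points_um: np.ndarray, max_distance_um: float = 25.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-nucleus minimum Delaunay-edge length and a clumping flag.

    Returns ``(min_dist, has_close_neighbor)`` where the flag is strict
    (``min_dist < max_distance_um``).  Edges longer than the cutoff are
    discarded before taking the minimum; a nucleus left with no edge gets
    NaN/False.  A single nucleus gets NaN/False.
    """
    points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
    n = len(points_um)
    min_dist = np.full(n, np.nan)
    if n >= 2:
        for i, j in _neighbor_graph(points_um):
            d = float(np.hypot(*(points_um[i] - points_um[j])))
            if d > max_distance_um:
                continue
            if not np.isfinite(min_dist[i]) or d < min_dist[i]:
                min_dist[i] = d
            if not np.isfinite(min_dist[j]) or d < min_dist[j]:
                min_dist[j] = d
    flags = np.where(np.isfinite(min_dist), min_dist < max_distance_um, False)
    return min_dist, flags.astype(bool)


def density_per_mm2(cells, region: RegionAnnotation) -> float:
    """Cell density in cells per mm² over the region's polygon area
    (holes subtracted by shapely's signed-area accounting).

    ``cells`` may be a count or an array of centroids.
    """
    n_cells = int(cells) if np.isscalar(cells) else len(np.atleast_2d(cells))
    area_mm2 = region.area_um2 / 1e6
    if area_mm2 <= 0:
        raise ValueError("region area must be positive")
    return n_cells / area_mm2


def nearest_neighbor_distance(points_um: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to the closest other point; NaN for a
    single point."""
    points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
    n = len(points_um)
    if n < 2:
        return np.full(n, np.nan)
    tree = cKDTree(points_um)
    dists, _ = tree.query(points_um, k=2)
    return dists[:, 1]
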