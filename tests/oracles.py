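"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (no scipy.spatial
Delaunay, no shapely area) so the implementations they check cannot share a
code path with them.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Set, Tuple

import numpy as np


def bowyer_watson_edges(points: np.ndarray) -> Set[Tuple[int, int]]:
    """Delaunay edge set via the Bowyer-Watson incremental algorithm.

    Plain-float implementation adequate for random (non-degenerate) point
    sets; returns undirected index pairs (i < j).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    # super-triangle comfortably containing everything
    cx, cy = pts.mean(axis=0)
    span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0) * 50.0
    sup = np.array(
        [[cx - 2 * span, cy - span], [cx + 2 * span, cy - span], [cx, cy + 2 * span]]
    )
    allp = np.vstack([pts, sup])
    S = [n, n + 1, n + 2]
    triangles: List[Tuple[int, int, int]] = [tuple(S)]

    def circumcircle(tri):
        ax, ay = allp[tri[0]]
        bx, by = allp[tri[1]]
        cx_, cy_ = allp[tri[2]]
        d = 2 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
        if d == 0:
            return (0.0, 0.0), math.inf
        ux = (
            (ax**2 + ay**2) * (by - cy_)
            + (bx**2 + by**2) * (cy_ - ay)
            + (cx_**2 + cy_**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx_ - bx)
            + (bx**2 + by**2) * (ax - cx_)
            + (cx_**2 + cy_**2) * (bx - ax)
        ) / d
        r = math.hypot(ax - ux, ay - uy)
        return (ux, uy), r

    circum = {tuple(S): circumcircle(S)}
    for i in range(n):
        px, py = allp[i]
        bad = []
        for tri in triangles:
            (ux, uy), r = circum[tri]
            if math.hypot(px - ux, py - uy) <= r * (1 + 1e-12):
                bad.append(tri)
        boundary = {}
        for tri in bad:
            for k in range(3):
                e = tuple(sorted((tri[k], tri[(k + 1) % 3])))
                boundary[e] = boundary.get(e, 0) + 1
        for tri in bad:
            triangles.remove(tri)
            circum.pop(tri, None)
        for e, count in boundary.items():
            if count == 1:
                tri = (e[0], e[1], i)
                triangles.append(tri)
                circum[tri] = circumcircle(tri)
    edges: Set[Tuple[int, int]] = set()
    for tri in triangles:
        if any(v >= n for v in tri):
            continue
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    return edges


def mean_neighbor_from_edges(
    points: np.ndarray, edges: Set[Tuple[int, int]], max_distance: float
) -> np.ndarray:
    out = np.full(len(points), np.nan)
    sums = np.zeros(len(points))
    counts = np.zeros(len(points), dtype=int)
    for i, j in edges:
        d = math.hypot(*(points[i] - points[j]))
        if d > max_distance:
            continue
        sums[i] += d
        sums[j] += d
        counts[i] += 1
        counts[j] += 1
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def shoelace_area(coords: Sequence[Tuple[float, float]]) -> float:
    """Signed-area magnitude of a simple polygon ring."""
    xs = np.array([c[0] for c in coords])
    ys = np.array([c[1] for c in coords])
    return 0.5 * abs(float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))))


def reactive_truth_table(cd68_pct: float, bi: int, neighbor_um) -> bool:
    """The three-threshold rule spelled out conjunct by conjunct."""
    if neighbor_um is None or (isinstance(neighbor_um, float) and math.isnan(neighbor_um)):
        return False
    return (cd68_pct >= 35.0) and (bi >= 1) and (neighbor_um < 25.0)


def decile_sizes(n: int, bins: int = 10) -> List[int]:
    base, rem = divmod(n, bins)
    return [base + 1] * rem + [base] * (bins - rem)
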