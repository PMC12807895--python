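"""Per-cell morphometric features from masks and intensity channels.

Shape descriptors follow the standard image-cytometry definitions:
``circularity = 4*pi*area / perimeter**2``, ``solidity = area / hull_area``,
``convexity = hull_perimeter / perimeter``, ``aspect_ratio = feret_max /
feret_min``.  The perimeter is the length of the traced boundary polygon
(marching squares at the 0.5 level) after a light 5-point circular smoothing
that removes pixel-staircase inflation, so a digitized disk reads circularity
~1.  Hull and Feret features come from the convex hull of the boundary
polygon; the minimum Feret diameter uses rotating calipers over hull edges.

Skeleton metrics mirror the classical branch analysis: the soma (nucleus
dilated by a few pixels) is deleted, the remaining processes are thinned to a
1-px 8-connected skeleton, and skeleton pixels are classified by neighbor
count.  Short spurs (thinning artifacts on stroked processes) are pruned, and
junction pixels are clustered so a thick fork counts as a single branch
point.  Skeleton endpoints adjacent to the deleted soma are branch roots, not
process tips, and are excluded from the endpoint count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.morphology import disk as disk_se
from skimage.morphology import skeletonize

from .core import centroid_px

_SMOOTH_WINDOW = 5
_SQ2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# shape features


def _boundary_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of the mask as a closed polygon in (row, col) pixel
    coordinates (padding-corrected)."""
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask has no boundary")
    poly = max(contours, key=len) - 1.0  # undo the pad
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def _smooth_closed(poly: np.ndarray, window: int = _SMOOTH_WINDOW) -> np.ndarray:
    n = len(poly)
    if n <= window:
        return poly
    k = window
    out = np.empty_like(poly)
    kern = np.ones(k) / k
    for j in range(poly.shape[1]):
        wrapped = np.r_[poly[-(k // 2):, j], poly[:, j], poly[: k // 2, j]]
        out[:, j] = np.convolve(wrapped, kern, "valid")[:n]
    return out


def _poly_length(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _hull_of(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (counter-clockwise); falls back to pixel-corner
    points for degenerate (collinear) boundaries such as 1-px lines."""
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except Exception:
        # degenerate: expand each point to a tiny square
        eps = 0.5
        expanded = np.concatenate(
            [points + [dr, dc] for dr in (-eps, eps) for dc in (-eps, eps)]
        )
        hull = ConvexHull(expanded)
        return expanded[hull.vertices]


def _feret_diameters(hull_pts: np.ndarray) -> Tuple[float, float]:
    """(max, min) Feret diameters via brute-force pairs (max) and rotating
    calipers over hull edges (min)."""
    n = len(hull_pts)
    if n == 1:
        return 0.0, 0.0
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    dists = np.hypot(diffs[..., 0], diffs[..., 1])
    fmax = float(dists.max())
    fmin = math.inf
    for i in range(n):
        p, q = hull_pts[i], hull_pts[(i + 1) % n]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = (hull_pts - p) @ normal
        fmin = min(fmin, float(proj.max() - proj.min()))
    if not math.isfinite(fmin):
        fmin = 0.0
    return fmax, fmin


def basic_shape_features(mask: np.ndarray, pixel_size_um: float) -> Dict[str, float]:
    """Area/perimeter/Feret/hull descriptors of a connected binary mask.

    Returns a dict with keys ``area_um2, perimeter_um, feret_max_um,
    feret_min_um, hull_area_um2, hull_perimeter_um, circularity, solidity,
    convexity, aspect_ratio``.
    """
    mask = np.asarray(mask, dtype=bool)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("cannot measure an empty mask")
    px = pixel_size_um
    poly = _boundary_polygon(mask)
    perimeter = _poly_length(_smooth_closed(poly)) * px
    hull_pts = _hull_of(poly)
    hull_perimeter = _poly_length(hull_pts) * px
    # shoelace on hull vertices
    x, y = hull_pts[:, 1], hull_pts[:, 0]
    hull_area = 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    ) * px**2
    fmax, fmin = _feret_diameters(hull_pts)
    area = area_px * px**2
    hull_area = max(hull_area, area)  # digitization: solidity <= 1
    return {
        "area_um2": area,
        "perimeter_um": perimeter,
        "feret_max_um": fmax * px,
        "feret_min_um": fmin * px,
        "hull_area_um2": hull_area,
        "hull_perimeter_um": hull_perimeter,
        "circularity": 4 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0,
        "solidity": area / hull_area if hull_area > 0 else 0.0,
        "convexity": hull_perimeter / perimeter if perimeter > 0 else 0.0,
        "aspect_ratio": fmax / fmin if fmin > 0 else float("inf"),
    }


# ---------------------------------------------------------------------------
# skeleton analysis

_OFFSETS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_OFFSETS_D = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


class _SkeletonGraph:
    """Pixel graph of a 1-px skeleton with AnalyzeSkeleton-style step weights
    (1 for 4-steps, sqrt(2) for diagonals; redundant diagonals that shortcut
    an existing 4-connected corner are dropped)."""

    def __init__(self, skel: np.ndarray):
        self.skel = skel
        coords = list(zip(*np.nonzero(skel)))
        self.nodes = coords
        self.index = {p: i for i, p in enumerate(coords)}
        self.adj: List[List[Tuple[int, float]]] = [[] for _ in coords]
        on = set(coords)
        for p in coords:
            r, c = p
            i = self.index[p]
            for dr, dc in _OFFSETS_4:
                q = (r + dr, c + dc)
                if q in on and self.index[q] > i:
                    self._add(i, self.index[q], 1.0)
            for dr, dc in _OFFSETS_D:
                q = (r + dr, c + dc)
                if q in on and self.index[q] > i:
                    # skip the diagonal if both share a 4-neighbor on the skeleton
                    if ((r, c + dc) in on) or ((r + dr, c) in on):
                        continue
                    self._add(i, self.index[q], _SQ2)

    def _add(self, i: int, j: int, w: float) -> None:
        self.adj[i].append((j, w))
        self.adj[j].append((i, w))

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def total_length(self) -> float:
        return sum(w for nbrs in self.adj for _, w in nbrs) / 2.0

    def walk_branches(self) -> List[Tuple[List[int], float]]:
        """Maximal degree-2 paths between nodes of degree != 2 (plus simple
        cycles); each returned as (node index path, length)."""
        branches = []
        visited = set()
        terminals = [i for i in range(len(self.nodes)) if self.degree(i) != 2]
        for t in terminals:
            for j, w in self.adj[t]:
                key = (min(t, j), max(t, j), round(w, 6))
                if (t, j) in visited or (j, t) in visited:
                    continue
                path = [t, j]
                visited.add((t, j))
                length = w
                prev, cur = t, j
                while self.degree(cur) == 2:
                    nxt = [(k, wk) for k, wk in self.adj[cur] if k != prev]
                    if not nxt:
                        break
                    (k, wk) = nxt[0]
                    if (cur, k) in visited or (k, cur) in visited:
                        break
                    visited.add((cur, k))
                    length += wk
                    path.append(k)
                    prev, cur = cur, k
                branches.append((path, length))
        # isolated cycles (every node degree 2)
        seen = {i for path, _ in branches for i in path}
        for i in range(len(self.nodes)):
            if i in seen or self.degree(i) != 2:
                continue
            path = [i]
            length = 0.0
            prev, cur = None, i
            while True:
                nxt = [(k, wk) for k, wk in self.adj[cur] if k != prev]
                if not nxt:
                    break
                k, wk = nxt[0]
                length += wk
                path.append(k)
                prev, cur = cur, k
                if cur == i:
                    break
            seen.update(path)
            branches.append((path, length))
        return branches


def _prune_spurs(skel: np.ndarray, min_len_px: float) -> np.ndarray:
    """Remove terminal branches shorter than ``min_len_px`` (thinning spurs)."""
    skel = skel.copy()
    for _ in range(3):  # a few passes; pruning can expose new spurs
        g = _SkeletonGraph(skel)
        removed = False
        for path, length in g.walk_branches():
            a, b = path[0], path[-1]
            deg_a, deg_b = g.degree(a), g.degree(b)
            is_spur = (
                length < min_len_px
                and ((deg_a == 1 and deg_b >= 3) or (deg_b == 1 and deg_a >= 3))
            )
            if is_spur:
                drop = path[:-1] if deg_b >= 3 else path[1:]
                for i in drop:
                    skel[g.nodes[i]] = False
                removed = True
        if not removed:
            break
    return skel


def skeletonize_and_analyze(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
    soma_dilation_px: int = 3,
    spur_px: float = 2.0,
    junction_merge_px: float = 3.0,
) -> Dict[str, float]:
    """Skeletonize the processes (cell minus dilated nucleus) and count.

    Returns ``skeleton_length_um``, ``n_junctions``, ``n_endpoints``,
    ``n_branches`` and ``branching_index`` (= the junction count).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    soma = ndi.binary_dilation(nucleus_mask, structure=disk_se(soma_dilation_px))
    processes = cell_mask & ~soma
    zero = {
        "skeleton_length_um": 0.0,
        "n_junctions": 0,
        "n_endpoints": 0,
        "n_branches": 0,
        "branching_index": 0,
    }
    if not processes.any():
        return zero
    skel = skeletonize(processes)
    if not skel.any():
        return zero
    # Thinning artifacts scale with the stroke width: a blunt tip of a
    # w-px-wide process thins into a "fishtail" spur of about w/2 px, and a
    # thick fork splits into two bifurcation pixels about w apart.  Estimate
    # the half-width from the distance transform under the skeleton and scale
    # the pruning length and junction merge radius accordingly.
    dist = ndi.distance_transform_edt(processes)
    half_width = float(np.median(dist[skel]))
    prune_len = max(spur_px, 1.7 * half_width + 1.0)
    merge_radius = max(junction_merge_px, 2.0 * half_width)
    skel = _prune_spurs(skel, prune_len)
    if not skel.any():
        return zero
    g = _SkeletonGraph(skel)

    # Endpoints: degree-1 pixels not sitting against the deleted soma (those
    # are branch roots, not process tips).  Thinning retracts skeleton ends
    # by about the stroke half-width, so the adjacency zone scales with it.
    near_soma = ndi.binary_dilation(
        soma, structure=disk_se(int(math.ceil(half_width)) + 2)
    )
    endpoints = [
        i
        for i in range(len(g.nodes))
        if g.degree(i) == 1 and not near_soma[g.nodes[i]]
    ]

    # junctions: cluster junction pixels, then merge clusters closer than the
    # stroke width (a thick fork thins into 2 nearby 3-way pixels)
    jmask = np.zeros_like(skel)
    for i in range(len(g.nodes)):
        if g.degree(i) >= 3:
            jmask[g.nodes[i]] = True
    lab, n_raw = ndi.label(jmask, structure=np.ones((3, 3), dtype=int))
    centers = ndi.center_of_mass(jmask, lab, range(1, n_raw + 1)) if n_raw else []
    n_junctions = _merge_count(np.array(centers, dtype=float), merge_radius)

    branches = g.walk_branches()
    return {
        "skeleton_length_um": g.total_length() * pixel_size_um,
        "n_junctions": int(n_junctions),
        "n_endpoints": len(endpoints),
        "n_branches": len(branches),
        "branching_index": int(n_junctions),
    }


def _merge_count(centers: np.ndarray, radius: float) -> int:
    """Number of clusters after single-linkage merging at the given radius."""
    n = len(centers)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(centers[i] - centers[j])) <= radius:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# intensity and offset features


def intensity_features(
    cell_mask: np.ndarray,
    iba1_channel: np.ndarray,
    cd68_channel: np.ndarray,
    cd68_threshold_au: float = 1000.0,
) -> Dict[str, float]:
    """Mean Iba1 over the cell and the CD68-positive area fraction.

    CD68 positivity is strict (``intensity > threshold``); the fraction is
    returned in [0, 1].
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n = int(cell_mask.sum())
    if n == 0:
        raise ValueError("cannot measure intensities on an empty mask")
    iba1_mean = float(iba1_channel[cell_mask].mean())
    cd68_pos = int((cd68_channel[cell_mask] > cd68_threshold_au).sum())
    return {"iba1_mean_au": iba1_mean, "cd68_area_fraction": cd68_pos / n}


def centroid_offset(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, pixel_size_um: float
) -> float:
    """Distance between the cell and nucleus pixel centroids, in μm."""
    cr, cc = centroid_px(np.asarray(cell_mask, dtype=bool))
    nr, nc = centroid_px(np.asarray(nucleus_mask, dtype=bool))
    return math.hypot(cr - nr, cc - nc) * pixel_size_um


# ---------------------------------------------------------------------------
# per-cell record


@dataclass
class CellFeatures:
    """The full per-cell record; one row of the feature table."""

    cell_id: int
    area_um2: float
    perimeter_um: float
    feret_max_um: float
    feret_min_um: float
    hull_area_um2: float
    hull_perimeter_um: float
    circularity: float
    solidity: float
    convexity: float
    aspect_ratio: float
    skeleton_length_um: float
    n_junctions: int
    n_endpoints: int
    n_branches: int
    branching_index: int
    branch_thickness_um: Optional[float]
    centroid_offset_um: float
    nucleus_area_um2: float
    nucleus_circularity: float
    iba1_mean_au: float
    cd68_area_fraction: float
    critical_radius_um: Optional[float] = None
    critical_value: int = 0
    n_primary: int = 0
    sri: Optional[float] = None
    delaunay_mean_neighbor_um: Optional[float] = None
    min_nucleus_neighbor_um: Optional[float] = None
    reactive: Optional[bool] = None
    region: str = ""
    animal_id: str = ""
    genotype: str = ""
    sex: str = ""

    def to_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)


def compute_cell_features(
    cell_id: int,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    iba1_channel: np.ndarray,
    cd68_channel: np.ndarray,
    pixel_size_um: float,
    cd68_threshold_au: float = 1000.0,
    soma_dilation_px: int = 3,
) -> CellFeatures:
    """All mask/intensity features for one cell (Sholl and spatial columns are
    filled in by their own modules)."""
    shape = basic_shape_features(cell_mask, pixel_size_um)
    nuc = basic_shape_features(nucleus_mask, pixel_size_um)
    skel = skeletonize_and_analyze(
        cell_mask, nucleus_mask, pixel_size_um, soma_dilation_px=soma_dilation_px
    )
    inten = intensity_features(cell_mask, iba1_channel, cd68_channel, cd68_threshold_au)
    offset = centroid_offset(cell_mask, nucleus_mask, pixel_size_um)
    cytoplasm = shape["area_um2"] - nuc["area_um2"]
    thick = (
        cytoplasm / skel["skeleton_length_um"]
        if skel["skeleton_length_um"] > 0
        else None
    )
    return CellFeatures(
        cell_id=cell_id,
        area_um2=shape["area_um2"],
        perimeter_um=shape["perimeter_um"],
        feret_max_um=shape["feret_max_um"],
        feret_min_um=shape["feret_min_um"],
        hull_area_um2=shape["hull_area_um2"],
        hull_perimeter_um=shape["hull_perimeter_um"],
        circularity=shape["circularity"],
        solidity=shape["solidity"],
        convexity=shape["convexity"],
        aspect_ratio=shape["aspect_ratio"],
        skeleton_length_um=skel["skeleton_length_um"],
        n_junctions=int(skel["n_junctions"]),
        n_endpoints=int(skel["n_endpoints"]),
        n_branches=int(skel["n_branches"]),
        branching_index=int(skel["branching_index"]),
        branch_thickness_um=thick,
        centroid_offset_um=offset,
        nucleus_area_um2=nuc["area_um2"],
        nucleus_circularity=nuc["circularity"],
        iba1_mean_au=inten["iba1_mean_au"],
        cd68_area_fraction=inten["cd68_area_fraction"],
    )
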