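"""Nucleus-anchored microglia segmentation.

The workflow mirrors the published semi-automated recipe:

1. *Pixel classification* of the Iba1 channel.  Here a configurable classical
   stand-in (Gaussian smooth + intensity threshold + small-object removal)
   produces the binary process mask; any externally computed binary mask with
   the same contract can be supplied instead.
2. *Nucleus segmentation* on the nuclear channel (smooth, threshold, fill,
   distance-transform peaks, marker watershed); a precomputed nucleus label
   mask may be passed through instead.
3. *Iba1⁺ nucleus filtering*: keep nuclei at least 30% Iba1-positive by area.
4. *Assembly*: per microglial nucleus, collect Iba1 detections within a
   collection radius of the nucleus centroid, close small gaps
   morphologically, keep the component contiguous with the nucleus, and union
   with the full nucleus.  Iba1 objects anchored to no nucleus are dropped.
5. *Separation*: pixels claimed by several candidate cells are partitioned by
   a marker-controlled watershed over geodesic distance from the anchor
   nucleus centroids (ties broken toward the lower label).
6. *QC*: drop cells whose nucleus touches the region boundary or lies outside
   the region, or whose nucleus/cell area is below the minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.graph import MCP_Geometric
from skimage.morphology import disk as disk_se
from skimage.segmentation import watershed

from .core import ChannelError, ImagePlane, MaskCrop, RegionAnnotation, centroid_px, relabel_sequential

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """All tunables of the segmentation chain (lengths/areas in μm)."""

    # Half-maximum between the typical background (~100 AU) and process
    # plateau (~2000 AU): the half-height level preserves object width under
    # Gaussian smoothing.
    iba1_threshold: float = 1050.0
    iba1_smooth_sigma_px: float = 1.0
    min_detection_size_um2: float = 0.2
    nucleus_min_fraction_iba1: float = 0.30
    collection_radius_um: float = 100.0
    closing_radius_px: int = 2
    max_nucleus_link_um: Optional[float] = None  # reserved; collection radius governs linking
    min_nucleus_area_um2: float = 5.0
    min_cell_area_um2: float = 50.0
    nucleus_threshold: Optional[float] = None  # None -> Otsu
    nucleus_smooth_sigma_px: float = 1.0
    nucleus_peak_min_distance_um: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "iba1_threshold",
            "iba1_smooth_sigma_px",
            "min_detection_size_um2",
            "collection_radius_um",
            "min_nucleus_area_um2",
            "min_cell_area_um2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.nucleus_min_fraction_iba1 <= 1:
            raise ValueError("nucleus_min_fraction_iba1 must be in [0, 1]")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")


@dataclass
class CellCandidate:
    """One nucleus-anchored candidate region (possibly overlapping others)."""

    anchor_label: int
    mask: MaskCrop
    nucleus_centroid_px: Tuple[float, float]


# ---------------------------------------------------------------------------


def classify_iba1_pixels(image: ImagePlane, params: SegmentationParams) -> np.ndarray:
    """Binary Iba1 process mask: smooth, threshold, drop tiny detections.

    Connected components with area strictly below ``min_detection_size_um2``
    are removed.
    """
    iba1 = image.channel("iba1").astype(float)
    if params.iba1_smooth_sigma_px > 0:
        iba1 = ndi.gaussian_filter(iba1, params.iba1_smooth_sigma_px)
    mask = iba1 >= params.iba1_threshold
    if not mask.any():
        return mask
    px2 = image.pixel_size_um**2
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = np.bincount(lab.ravel())
        small = np.nonzero(areas * px2 < params.min_detection_size_um2)[0]
        small = small[small > 0]
        if small.size:
            mask &= ~np.isin(lab, small)
    return mask


def segment_nuclei(
    image: ImagePlane,
    params: SegmentationParams,
    external_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Nucleus label mask from the nuclear channel (or a validated external
    mask from any segmenter, e.g. a deep-learning model run elsewhere)."""
    if external_mask is not None:
        external_mask = np.asarray(external_mask)
        if external_mask.shape != image.shape:
            raise ValueError(
                f"external nucleus mask shape {external_mask.shape} does not "
                f"match image shape {image.shape}"
            )
        if external_mask.min() < 0:
            raise ValueError("external nucleus mask has negative labels")
        return relabel_sequential(external_mask.astype(np.int32))

    chan = image.channel("nuclear").astype(float)
    if params.nucleus_smooth_sigma_px > 0:
        chan = ndi.gaussian_filter(chan, params.nucleus_smooth_sigma_px)
    if params.nucleus_threshold is not None:
        thresh = params.nucleus_threshold
    else:
        if np.ptp(chan) == 0:
            logger.info("blank nuclear channel: empty nucleus mask")
            return np.zeros(image.shape, dtype=np.int32)
        thresh = float(threshold_otsu(chan))
    fg = chan > thresh
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        logger.info("nucleus segmentation found nothing")
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    min_dist_px = max(2, int(round(params.nucleus_peak_min_distance_um / image.pixel_size_um)))
    peaks = peak_local_max(dist, min_distance=min_dist_px, labels=fg, exclude_border=False)
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        lab, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
        return lab.astype(np.int32)
    labels = watershed(-dist, markers, mask=fg)
    return relabel_sequential(labels.astype(np.int32))


def filter_iba1_positive_nuclei(
    nuclei: np.ndarray, iba1_mask: np.ndarray, min_fraction: float = 0.30
) -> np.ndarray:
    """Keep nuclei whose Iba1⁺ pixel fraction is >= ``min_fraction``
    (boundary-inclusive); relabel contiguously."""
    nuclei = np.asarray(nuclei)
    iba1_mask = np.asarray(iba1_mask, dtype=bool)
    if nuclei.shape != iba1_mask.shape:
        raise ValueError("shape mismatch between nuclei and Iba1 mask")
    n = int(nuclei.max())
    if n == 0:
        return nuclei.astype(np.int32)
    total = np.bincount(nuclei.ravel(), minlength=n + 1).astype(float)
    pos = np.bincount(nuclei.ravel(), weights=iba1_mask.ravel(), minlength=n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, pos / total, 0.0)
    keep = [lbl for lbl in range(1, n + 1) if total[lbl] > 0 and frac[lbl] >= min_fraction]
    return relabel_sequential(nuclei.astype(np.int32), keep=keep)


def assemble_microglia(
    iba1_mask: np.ndarray,
    microglial_nuclei: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> List[CellCandidate]:
    """Build one candidate cell region per microglial nucleus.

    For each nucleus: restrict the Iba1 mask to the collection disk around
    the nucleus centroid, close small gaps, keep the connected component(s)
    touching the nucleus, and union with the full nucleus.  A nucleus with no
    adjacent Iba1 signal yields a nucleus-only candidate (logged; it will
    normally fail the minimum-cell-area QC).
    """
    iba1_mask = np.asarray(iba1_mask, dtype=bool)
    microglial_nuclei = np.asarray(microglial_nuclei)
    if iba1_mask.shape != microglial_nuclei.shape:
        raise ValueError("shape mismatch between Iba1 mask and nuclei")
    h, w = iba1_mask.shape
    r_collect = params.collection_radius_um / pixel_size_um
    pad = params.closing_radius_px + 1
    candidates: List[CellCandidate] = []
    struct8 = np.ones((3, 3), dtype=int)
    se_close = disk_se(params.closing_radius_px) if params.closing_radius_px > 0 else None

    n_labels = int(microglial_nuclei.max())
    slices = ndi.find_objects(microglial_nuclei, max_label=n_labels)
    for lbl in range(1, n_labels + 1):
        sl = slices[lbl - 1]
        if sl is None:
            continue
        nuc_local = microglial_nuclei[sl] == lbl
        rloc, cloc = np.nonzero(nuc_local)
        cen = (
            float(rloc.mean()) + sl[0].start,
            float(cloc.mean()) + sl[1].start,
        )
        r0 = max(int(math.floor(cen[0] - r_collect)) - pad, 0)
        c0 = max(int(math.floor(cen[1] - r_collect)) - pad, 0)
        r1 = min(int(math.ceil(cen[0] + r_collect)) + pad + 1, h)
        c1 = min(int(math.ceil(cen[1] + r_collect)) + pad + 1, w)
        crop = iba1_mask[r0:r1, c0:c1]
        rows, cols = np.mgrid[r0:r1, c0:c1]
        within = (rows - cen[0]) ** 2 + (cols - cen[1]) ** 2 <= r_collect**2
        work = crop & within
        if se_close is not None:
            work = ndi.binary_closing(np.pad(work, pad), structure=se_close)[
                pad:-pad, pad:-pad
            ]
        nuc_crop = microglial_nuclei[r0:r1, c0:c1] == lbl
        lab, ncomp = ndi.label(work | nuc_crop, structure=struct8)
        touching = np.unique(lab[nuc_crop])
        touching = touching[touching > 0]
        cell = np.isin(lab, touching) if touching.size else nuc_crop.copy()
        cell |= nuc_crop
        if cell.sum() <= nuc_crop.sum():
            logger.info("nucleus %d has no adjacent Iba1 signal", lbl)
        candidates.append(
            CellCandidate(
                anchor_label=lbl,
                mask=MaskCrop(cell, (r0, c0)),
                nucleus_centroid_px=cen,
            )
        )
    return candidates


def separate_overlapping(
    candidates: Sequence[CellCandidate],
    nuclei: np.ndarray,
    shape: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Partition overlapping candidates into disjoint cells.

    Overlap pixels go to the candidate whose anchor-nucleus centroid is
    geodesically closest within that candidate's own mask; ties break toward
    the lower anchor label.  Union of the output equals the union of the
    candidates, each cell stays connected and contains its full nucleus.
    """
    nuclei = np.asarray(nuclei)
    if shape is None:
        shape = nuclei.shape
    cells = np.zeros(shape, dtype=np.int32)
    claims = np.zeros(shape, dtype=np.int16)
    for cand in candidates:
        r, c = cand.mask.pixels()
        claims[r, c] += 1

    # single claims: assign directly (later writes can't collide)
    for cand in candidates:
        r, c = cand.mask.pixels()
        single = claims[r, c] == 1
        cells[r[single], c[single]] = cand.anchor_label

    overlap = claims >= 2
    if overlap.any():
        best = np.full(shape, np.inf)
        for cand in sorted(candidates, key=lambda c: c.anchor_label):
            r, c = cand.mask.pixels()
            if not overlap[r, c].any():
                continue
            dist = _geodesic_distances(cand)
            rr, cc = cand.mask.pixels()
            mine = overlap[rr, cc]
            rr, cc = rr[mine], cc[mine]
            d = dist[rr - cand.mask.offset[0], cc - cand.mask.offset[1]]
            better = d < best[rr, cc]  # strict: ties keep the lower label
            cells[rr[better], cc[better]] = cand.anchor_label
            best[rr[better], cc[better]] = d[better]

    # each nucleus belongs to its own cell
    for cand in candidates:
        cells[nuclei == cand.anchor_label] = cand.anchor_label

    _reconnect(cells, candidates, nuclei)
    return cells


def _geodesic_distances(cand: CellCandidate) -> np.ndarray:
    """Geodesic distance from the anchor centroid within the candidate mask."""
    mask = cand.mask.array
    costs = np.where(mask, 1.0, np.inf)
    start = (
        int(round(cand.nucleus_centroid_px[0])) - cand.mask.offset[0],
        int(round(cand.nucleus_centroid_px[1])) - cand.mask.offset[1],
    )
    start = (
        min(max(start[0], 0), mask.shape[0] - 1),
        min(max(start[1], 0), mask.shape[1] - 1),
    )
    if not mask[start]:
        r, c = np.nonzero(mask)
        i = int(np.argmin((r - start[0]) ** 2 + (c - start[1]) ** 2))
        start = (int(r[i]), int(c[i]))
    mcp = MCP_Geometric(costs)
    dist, _ = mcp.find_costs([start])
    return dist


def _reconnect(cells: np.ndarray, candidates: Sequence[CellCandidate], nuclei: np.ndarray) -> None:
    """Reassign components disconnected from their nucleus to an adjacent
    cell (majority of touching labels); keeps the union of pixels intact."""
    struct8 = np.ones((3, 3), dtype=int)
    for _ in range(3):
        changed = False
        for cand in candidates:
            lbl = cand.anchor_label
            r0, c0 = cand.mask.offset
            hh, ww = cand.mask.array.shape
            sub = cells[r0 : r0 + hh, c0 : c0 + ww]
            mine = sub == lbl
            if not mine.any():
                continue
            comp, n = ndi.label(mine, structure=struct8)
            if n <= 1:
                continue
            nuc_sub = nuclei[r0 : r0 + hh, c0 : c0 + ww] == lbl
            anchor_comps = np.unique(comp[nuc_sub])
            anchor_comps = anchor_comps[anchor_comps > 0]
            keep = set(int(a) for a in anchor_comps) or {1}
            for k in range(1, n + 1):
                if k in keep:
                    continue
                part = comp == k
                ring = ndi.binary_dilation(part, structure=struct8) & ~part
                neighbor_labels = sub[ring]
                neighbor_labels = neighbor_labels[
                    (neighbor_labels > 0) & (neighbor_labels != lbl)
                ]
                if neighbor_labels.size:
                    new = int(np.bincount(neighbor_labels).argmax())
                    sub[part] = new
                    changed = True
        if not changed:
            break


def apply_qc_filters(
    cells: np.ndarray,
    nuclei: np.ndarray,
    region: RegionAnnotation,
    params: SegmentationParams,
    pixel_size_um: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Remove boundary-touching and undersized cells; relabel 1..K so cell
    and nucleus labels match.  Returns ``(cells, nuclei)``.

    A cell is removed when its nucleus intersects the rasterized 1-px region
    boundary, lies entirely outside the region, or when ``nucleus area <
    min_nucleus_area_um2`` or ``cell area < min_cell_area_um2`` (both strict,
    so boundary values are kept).  Idempotent on its own output.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    px2 = pixel_size_um**2
    region_mask = region.to_mask(cells.shape, pixel_size_um)
    boundary = region_mask ^ ndi.binary_erosion(region_mask, border_value=0)
    n = int(max(cells.max(), nuclei.max()))
    nuc_areas = np.bincount(nuclei.ravel(), minlength=n + 1)
    cell_areas = np.bincount(cells.ravel(), minlength=n + 1)
    on_boundary = set(np.unique(nuclei[boundary])) - {0}
    inside_counts = np.bincount(nuclei[region_mask].ravel(), minlength=n + 1)
    keep: List[int] = []
    for lbl in range(1, n + 1):
        if nuc_areas[lbl] == 0 or cell_areas[lbl] == 0:
            continue
        if lbl in on_boundary:
            continue
        if inside_counts[lbl] == 0:  # nucleus entirely outside: ignore
            continue
        if nuc_areas[lbl] * px2 < params.min_nucleus_area_um2:
            continue
        if cell_areas[lbl] * px2 < params.min_cell_area_um2:
            continue
        keep.append(lbl)
    return (
        relabel_sequential(cells.astype(np.int32), keep=keep),
        relabel_sequential(nuclei.astype(np.int32), keep=keep),
    )


def segment_cells(
    image: ImagePlane,
    region: RegionAnnotation,
    params: Optional[SegmentationParams] = None,
    external_nuclei: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Run the full segmentation chain; returns matched (cells, nuclei)
    label masks after QC."""
    params = params or SegmentationParams()
    iba1_mask = classify_iba1_pixels(image, params)
    nuclei = segment_nuclei(image, params, external_mask=external_nuclei)
    nuclei = filter_iba1_positive_nuclei(
        nuclei, iba1_mask, params.nucleus_min_fraction_iba1
    )
    candidates = assemble_microglia(iba1_mask, nuclei, params, image.pixel_size_um)
    cells = separate_overlapping(candidates, nuclei, shape=image.shape)
    return apply_qc_filters(cells, nuclei, region, params, image.pixel_size_um)
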