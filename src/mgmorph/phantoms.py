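"""Synthetic fluorescence scenes of microglia with exact ground truth.

Cells are built as 2D polyline trees: a soma disk with primary processes that
recursively fork, each stroked at a constant per-phenotype thickness.  Because
the tree is explicit, the generator knows the true skeleton length, junction
count, endpoint count and primary-branch count of every cell — downstream
segmentation and morphometry can therefore be tested for parameter recovery
without any real images.

Four phenotype presets mirror the classical microglial activation continuum:

* ``ramified`` — surveillant: thin, moderately branched arbor, low CD68.
* ``hyper_ramified`` — primed: more primaries, deeper and longer branching.
* ``reactive`` — retracted, thick, short processes, high granular CD68;
  typically placed in spatial clusters.
* ``amoeboid`` — soma only (no processes), thickest "branch" stroke, high CD68.

Preset geometry values are conventions of this generator (the activation
literature describes the states qualitatively, not with branch-count recipes);
the invariants between presets — hyper-ramified strictly more/longer branches
than ramified, amoeboid depth <= 1 with the thickest stroke, reactive CD68
fraction >= 0.35 while ramified < 0.35 — are what the tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk as disk_se

from .core import ImagePlane, MaskCrop

DEFAULT_PIXEL_SIZE_UM = 0.172


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed within the retry budget."""


@dataclass(frozen=True)
class PhenotypePreset:
    """Geometry and staining recipe for one phenotype."""

    name: str
    n_primary_branches: int
    branch_depth: int
    segment_length_um: float
    branch_thickness_um: float
    soma_radius_um: float
    cd68_granule_fraction: float
    tortuosity: float = 0.15
    children_per_branch: int = 2
    child_prob: float = 0.9
    fork_half_angle: float = 0.55  # radians
    length_decay: float = 0.85

    def __post_init__(self) -> None:
        if self.n_primary_branches < 0 or self.branch_depth < 0:
            raise ValueError("branch counts must be non-negative")
        if self.segment_length_um <= 0 or self.branch_thickness_um <= 0:
            raise ValueError("lengths must be positive")
        if self.soma_radius_um <= 0:
            raise ValueError("soma_radius_um must be positive")
        if not 0 <= self.cd68_granule_fraction <= 1:
            raise ValueError("cd68_granule_fraction must be in [0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be non-negative")

    def max_reach_um(self) -> float:
        """Upper bound on the distance from soma center to any branch tip."""
        reach = self.soma_radius_um
        length = self.segment_length_um
        for _ in range(self.branch_depth):
            reach += length
            length *= self.length_decay
        return reach + self.branch_thickness_um


PRESETS: Dict[str, PhenotypePreset] = {
    "ramified": PhenotypePreset(
        "ramified", n_primary_branches=4, branch_depth=3, segment_length_um=8.0,
        branch_thickness_um=0.6, soma_radius_um=3.0, cd68_granule_fraction=0.10,
        tortuosity=0.15,
    ),
    "hyper_ramified": PhenotypePreset(
        "hyper_ramified", n_primary_branches=5, branch_depth=4, segment_length_um=10.0,
        branch_thickness_um=0.6, soma_radius_um=3.0, cd68_granule_fraction=0.10,
        tortuosity=0.2,
    ),
    # child_prob 1: a cell carrying the "reactive" label must express the
    # branching its operational definition demands (>= 1 branch point)
    "reactive": PhenotypePreset(
        "reactive", n_primary_branches=3, branch_depth=2, segment_length_um=4.0,
        branch_thickness_um=1.5, soma_radius_um=3.5, cd68_granule_fraction=0.45,
        tortuosity=0.1, child_prob=1.0,
    ),
    "amoeboid": PhenotypePreset(
        "amoeboid", n_primary_branches=0, branch_depth=0, segment_length_um=1.0,
        branch_thickness_um=2.5, soma_radius_um=5.0, cd68_granule_fraction=0.50,
        tortuosity=0.0,
    ),
}


@dataclass
class Branch:
    """One branch of a phantom tree as a polyline in scene μm coordinates."""

    points: np.ndarray  # (N, 2) array of (x, y) in μm
    depth: int
    parent: int  # index into the cell's branch list; -1 for primaries

    @property
    def length_um(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class TruthCell:
    """Ground truth for one rendered cell."""

    phenotype: str
    center_um: Tuple[float, float]  # (x, y) soma/nucleus center
    cell_mask: MaskCrop
    nucleus_mask: MaskCrop
    granule_mask: MaskCrop
    branches: List[Branch]
    n_primary: int
    n_junctions: int
    n_endpoints: int
    skeleton_length_um: float
    cd68_fraction: float  # achieved granule coverage of the cell mask

    @property
    def area_um2(self) -> float:  # convenience for tests
        raise AttributeError("use cell_mask.area_px * pixel_size**2")


@dataclass
class SceneConfig:
    """Full description of one synthetic scene; the scene is a pure function
    of this config (identical config + seed => bit-identical image)."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells_per_phenotype: Dict[str, int] = field(default_factory=dict)
    cluster_center_um: Optional[Tuple[float, float]] = None
    cluster_radius_um: float = 25.0
    clustered_phenotypes: Tuple[str, ...] = ("reactive",)
    # every clustered cell keeps a nucleus neighbor under this distance
    cluster_chain_um: float = 24.0
    # microglia tile the parenchyma with largely non-overlapping territories;
    # 60 μm keeps two full ramified arbors (reach ~28 μm) disjoint
    min_separation_um: float = 60.0
    # clustered cells sit close enough to satisfy the 25 μm clump rule but
    # far enough apart (> soma diameter + proximal arbor) that each keeps
    # its own processes; real reactive clumps are loose chains, not fusions
    cluster_min_separation_um: float = 15.0
    noise_sd: float = 20.0
    blur_sigma_px: float = 1.0
    rng_seed: int = 0
    max_placement_retries: int = 100
    intensity_levels: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "nuclear": (100.0, 1500.0),
            "cd68": (100.0, 2000.0),
            "iba1": (100.0, 2000.0),
        }
    )

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be non-negative")
        for name, n in self.n_cells_per_phenotype.items():
            if n < 0:
                raise ValueError(f"negative cell count for {name!r}")
            if name not in PRESETS:
                raise ValueError(f"unknown phenotype {name!r}")
        for ch in ("nuclear", "cd68", "iba1"):
            if ch not in self.intensity_levels:
                raise ValueError(f"intensity_levels missing channel {ch!r}")


@dataclass
class PhantomScene:
    image: ImagePlane
    truth_cells: List[TruthCell]
    config: SceneConfig


# ---------------------------------------------------------------------------
# single-cell rendering


def _grow_tree(
    preset: PhenotypePreset,
    center: Tuple[float, float],
    rng: np.random.Generator,
) -> Tuple[List[Branch], int, int, int]:
    """Grow a *self-avoiding* polyline tree; returns (branches, n_primary,
    n_junctions, n_endpoints).

    Self-avoidance keeps distinct branch strokes from merging in the raster,
    so the recorded tree topology (junctions = nodes with >= 2 children,
    endpoints = leaves) stays consistent with the rendered mask.  A child
    whose every candidate angle collides with existing branches is dropped;
    counts describe the realized tree.
    """
    branches: List[Branch] = []
    occupied: List[np.ndarray] = []  # 0.5 μm-spaced samples of all strokes
    n_junctions = 0
    n_endpoints = 0
    clearance = max(1.8, preset.branch_thickness_um + 1.2)
    fork_excl = 2.0  # μm around a fork where adjacency is expected

    def resample(poly: np.ndarray) -> np.ndarray:
        d = np.diff(poly, axis=0)
        seglen = np.hypot(d[:, 0], d[:, 1])
        total = seglen.sum()
        n = max(2, int(math.ceil(total / 0.5)))
        t = np.linspace(0.0, total, n)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        return np.column_stack(
            [np.interp(t, cum, poly[:, 0]), np.interp(t, cum, poly[:, 1])]
        )

    def collides(poly: np.ndarray, start: np.ndarray) -> bool:
        samples = resample(poly)
        # self-fold: two samples far apart along the arc but close in space
        n = len(samples)
        if n > 4:
            sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) * 0.5
            d_self = np.hypot(
                *(samples[:, None, :] - samples[None, :, :]).transpose(2, 0, 1)
            )
            if bool(((sep > fork_excl) & (d_self < clearance)).any()):
                return True
        if not occupied:
            return False
        existing = np.concatenate(occupied)
        far_own = np.hypot(*(samples - start).T) > fork_excl
        far_other = np.hypot(*(existing - start).T) > fork_excl
        if not far_own.any() or not far_other.any():
            return False
        d = np.hypot(
            *(samples[far_own][:, None, :] - existing[far_other][None, :, :]).transpose(2, 0, 1)
        )
        return bool((d < clearance).any())

    def make_polyline(start: np.ndarray, angle: float, depth: int) -> np.ndarray:
        length = preset.segment_length_um * preset.length_decay**depth
        step = max(0.5, length / 8.0)
        n_steps = max(1, int(round(length / step)))
        pts = [start]
        a = angle
        for _ in range(n_steps):
            if preset.tortuosity > 0:
                a += rng.normal(0.0, preset.tortuosity)
            pts.append(pts[-1] + step * np.array([math.cos(a), math.sin(a)]))
        return np.array(pts)

    def try_grow(start: np.ndarray, angle: float, depth: int, parent: int) -> bool:
        """Grow one branch at ~angle, retrying jittered angles on collision."""
        nonlocal n_junctions, n_endpoints
        for attempt in range(5):
            a = angle if attempt == 0 else angle + rng.normal(0.0, 0.35)
            poly = make_polyline(start, a, depth)
            if not collides(poly, start):
                break
        else:
            return False
        idx = len(branches)
        branches.append(Branch(points=poly, depth=depth, parent=parent))
        occupied.append(resample(poly))
        end_angle = math.atan2(*(poly[-1] - poly[-2])[::-1])
        if depth + 1 >= preset.branch_depth:
            n_endpoints += 1
            return True
        kids = [
            k
            for k in range(preset.children_per_branch)
            if preset.child_prob >= 1.0 or rng.random() < preset.child_prob
        ]
        spread = preset.fork_half_angle
        if len(kids) <= 1:
            child_angles = [end_angle + rng.normal(0.0, 0.15)] if kids else []
        else:
            offs = np.linspace(-spread, spread, len(kids))
            child_angles = [end_angle + o + rng.normal(0.0, 0.08) for o in offs]
        grown = sum(try_grow(poly[-1], ca, depth + 1, idx) for ca in child_angles)
        if grown >= 2:
            n_junctions += 1
        if grown == 0:
            n_endpoints += 1
        return True

    n_primary = 0
    if preset.branch_depth > 0 and preset.n_primary_branches > 0:
        k_total = preset.n_primary_branches
        base = rng.uniform(0.0, 2 * math.pi)
        for k in range(k_total):
            ang = base + 2 * math.pi * k / k_total + rng.normal(0.0, 0.12)
            start = np.array(center) + (preset.soma_radius_um * 0.9) * np.array(
                [math.cos(ang), math.sin(ang)]
            )
            if try_grow(start, ang, 0, -1):
                n_primary += 1
    return branches, n_primary, n_junctions, n_endpoints


def _stroke_branches(
    branches: Sequence[Branch],
    thickness_um: float,
    pixel_size_um: float,
    offset_px: Tuple[int, int],
    shape: Tuple[int, int],
) -> np.ndarray:
    """Rasterize polylines into a crop canvas and thicken to the stroke width."""
    canvas = np.zeros(shape, dtype=bool)
    r0, c0 = offset_px
    for br in branches:
        pts = br.points
        d = np.diff(pts, axis=0)
        seglen = np.hypot(d[:, 0], d[:, 1])
        total = seglen.sum()
        if total <= 0:
            continue
        n = max(2, int(math.ceil(total / (0.3 * pixel_size_um))))
        t = np.linspace(0.0, total, n)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        xs = np.interp(t, cum, pts[:, 0])
        ys = np.interp(t, cum, pts[:, 1])
        rr = np.round(ys / pixel_size_um).astype(int) - r0
        cc = np.round(xs / pixel_size_um).astype(int) - c0
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    radius = max(1, int(round(thickness_um / 2.0 / pixel_size_um)))
    return ndi.binary_dilation(canvas, structure=disk_se(radius))


def render_cell(
    preset: PhenotypePreset,
    center_um: Tuple[float, float],
    rng: np.random.Generator,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    canvas_shape: Optional[Tuple[int, int]] = None,
) -> TruthCell:
    """Render one cell's ground truth (masks + tree) at a given soma center.

    The cell mask is the union of the soma disk and the stroked branch
    polylines; the nucleus is an ellipse inside the soma.  If ``canvas_shape``
    is given and the cell's reach would overflow it, a :class:`PlacementError`
    is raised (scene rendering treats that as "resample the center").
    """
    px = pixel_size_um
    reach = preset.max_reach_um()
    cx, cy = center_um
    if canvas_shape is not None:
        h, w = canvas_shape
        if (
            cx - reach < -0.5 * px
            or cy - reach < -0.5 * px
            or cx + reach > (w - 0.5) * px
            or cy + reach > (h - 0.5) * px
        ):
            raise PlacementError(
                f"cell at ({cx:.1f}, {cy:.1f}) μm with reach {reach:.1f} μm "
                "overflows the canvas"
            )

    branches, n_primary, n_junctions, n_endpoints = _grow_tree(preset, (cx, cy), rng)
    skeleton_length = float(sum(b.length_um for b in branches))

    # crop geometry
    pad = 2
    r_lo = int(math.floor((cy - reach) / px)) - pad
    c_lo = int(math.floor((cx - reach) / px)) - pad
    r_hi = int(math.ceil((cy + reach) / px)) + pad + 1
    c_hi = int(math.ceil((cx + reach) / px)) + pad + 1
    if canvas_shape is not None:
        r_lo, c_lo = max(r_lo, 0), max(c_lo, 0)
        r_hi = min(r_hi, canvas_shape[0])
        c_hi = min(c_hi, canvas_shape[1])
    shape = (r_hi - r_lo, c_hi - c_lo)

    cell = _stroke_branches(branches, preset.branch_thickness_um, px, (r_lo, c_lo), shape)
    # soma disk
    rows, cols = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dist2 = (cols * px - cx) ** 2 + (rows * px - cy) ** 2
    cell |= dist2 <= preset.soma_radius_um**2

    # Nucleus: ellipse nearly filling the soma (microglia carry scant
    # perinuclear cytoplasm), so that the standard soma deletion
    # (nucleus dilated by 3 px) covers the whole soma disk and no annulus
    # survives skeletonization.
    a = max(0.75 * preset.soma_radius_um, preset.soma_radius_um - 0.15) / px
    b = max(0.60 * preset.soma_radius_um, preset.soma_radius_um - 0.35) / px
    theta = rng.uniform(0.0, math.pi)
    rr, cc = draw_ellipse(
        cy / px - r_lo, cx / px - c_lo, a, b, shape=shape, rotation=theta
    )
    nucleus = np.zeros(shape, dtype=bool)
    nucleus[rr, cc] = True
    cell |= nucleus  # digitization safety: nucleus always inside cell

    granules, frac = _draw_granules(cell, preset.cd68_granule_fraction, px, rng)

    return TruthCell(
        phenotype=preset.name,
        center_um=(cx, cy),
        cell_mask=MaskCrop(cell, (r_lo, c_lo)),
        nucleus_mask=MaskCrop(nucleus, (r_lo, c_lo)),
        granule_mask=MaskCrop(granules, (r_lo, c_lo)),
        branches=branches,
        n_primary=n_primary,
        n_junctions=n_junctions,
        n_endpoints=n_endpoints,
        skeleton_length_um=skeleton_length,
        cd68_fraction=frac,
    )


def _draw_granules(
    cell: np.ndarray,
    target_fraction: float,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float]:
    """Random disks inside the cell mask until coverage reaches the target."""
    granules = np.zeros_like(cell)
    area = cell.sum()
    if target_fraction <= 0 or area == 0:
        return granules, 0.0
    r_cells, c_cells = np.nonzero(cell)
    r_px = max(1, int(round(0.45 / pixel_size_um)))
    se = disk_se(r_px)
    sr = r_px
    for _ in range(10000):
        covered = granules.sum() / area
        if covered >= target_fraction:
            break
        i = rng.integers(0, len(r_cells))
        r0, c0 = r_cells[i], c_cells[i]
        rlo, clo = max(r0 - sr, 0), max(c0 - sr, 0)
        rhi = min(r0 + sr + 1, cell.shape[0])
        chi = min(c0 + sr + 1, cell.shape[1])
        patch = se[
            rlo - (r0 - sr) : 2 * sr + 1 - ((r0 + sr + 1) - rhi),
            clo - (c0 - sr) : 2 * sr + 1 - ((c0 + sr + 1) - chi),
        ].astype(bool)
        granules[rlo:rhi, clo:chi] |= patch & cell[rlo:rhi, clo:chi]
    return granules, float(granules.sum() / area)


# ---------------------------------------------------------------------------
# scene rendering


def _sample_center(
    preset: PhenotypePreset,
    config: SceneConfig,
    rng: np.random.Generator,
    clustered: bool,
) -> Tuple[float, float]:
    px = config.pixel_size_um
    w_um = (config.width_px - 1) * px
    h_um = (config.height_px - 1) * px
    margin = preset.max_reach_um() + 2 * px
    if clustered:
        if config.cluster_center_um is None:
            cx0 = w_um / 2.0
            cy0 = h_um / 2.0
        else:
            cx0, cy0 = config.cluster_center_um
        rad = config.cluster_radius_um * math.sqrt(rng.random())
        ang = rng.uniform(0, 2 * math.pi)
        return (cx0 + rad * math.cos(ang), cy0 + rad * math.sin(ang))
    if w_um <= 2 * margin or h_um <= 2 * margin:
        raise PlacementError(
            f"canvas too small for phenotype {preset.name!r} (margin {margin:.1f} μm)"
        )
    return (rng.uniform(margin, w_um - margin), rng.uniform(margin, h_um - margin))


def render_scene(config: SceneConfig) -> PhantomScene:
    """Render a full scene; ground truth is recorded before blur and noise."""
    rng = np.random.default_rng(config.rng_seed)
    px = config.pixel_size_um
    shape = (config.height_px, config.width_px)

    placements: List[Tuple[float, float]] = []
    sep_kinds: List[bool] = []  # True if clustered placement
    cells: List[TruthCell] = []

    # deterministic order, clustered phenotypes first so the cluster site is
    # reserved before free placements can block it
    order = sorted(
        config.n_cells_per_phenotype,
        key=lambda n: (n not in config.clustered_phenotypes, n),
    )
    def separation_ok(center, clustered):
        for (ox, oy), other_clustered in zip(placements, sep_kinds):
            need = (
                config.cluster_min_separation_um
                if (clustered and other_clustered)
                else config.min_separation_um
            )
            if (center[0] - ox) ** 2 + (center[1] - oy) ** 2 < need**2:
                return False
        return True

    def chain_ok(center):
        """Clustered cells form a loose chain: each (after the first) must
        have a clustered neighbor closer than cluster_chain_um."""
        members = [p for p, k in zip(placements, sep_kinds) if k]
        if not members:
            return True
        return any(
            (center[0] - ox) ** 2 + (center[1] - oy) ** 2 < config.cluster_chain_um**2
            for ox, oy in members
        )

    def place_one(preset, clustered, tries):
        for _ in range(tries):
            center = _sample_center(preset, config, rng, clustered)
            if not separation_ok(center, clustered):
                continue
            if clustered and not chain_ok(center):
                continue
            try:
                cell = render_cell(preset, center, rng, px, canvas_shape=shape)
            except PlacementError:
                continue
            placements.append(center)
            sep_kinds.append(clustered)
            cells.append(cell)
            return True
        return False

    for name in order:
        preset = PRESETS[name]
        clustered = name in config.clustered_phenotypes
        count = config.n_cells_per_phenotype[name]
        if clustered and count > 0:
            # tight packings can dead-end; restart the whole cluster rather
            # than fail on an unlucky partial layout (bounded, seed-driven)
            placed_all = False
            for _restart in range(config.max_placement_retries):
                mark = len(cells)
                if all(place_one(preset, True, 30) for _ in range(count)):
                    placed_all = True
                    break
                del placements[mark:], sep_kinds[mark:], cells[mark:]
            if not placed_all:
                raise PlacementError(
                    f"could not place the {name!r} cluster after "
                    f"{config.max_placement_retries} restarts"
                )
        else:
            for _ in range(count):
                if not place_one(preset, False, config.max_placement_retries):
                    raise PlacementError(
                        f"could not place a {name!r} cell after "
                        f"{config.max_placement_retries} retries"
                    )

    channels = {}
    for ch in ("nuclear", "cd68", "iba1"):
        bg, _fg = config.intensity_levels[ch]
        channels[ch] = np.full(shape, bg, dtype=np.float32)

    for cell in cells:
        fg_iba1 = config.intensity_levels["iba1"][1]
        fg_nuc = config.intensity_levels["nuclear"][1]
        fg_cd68 = config.intensity_levels["cd68"][1]
        r, c = cell.cell_mask.pixels()
        np.maximum.at(channels["iba1"], (r, c), fg_iba1)
        r, c = cell.nucleus_mask.pixels()
        np.maximum.at(channels["nuclear"], (r, c), fg_nuc)
        r, c = cell.granule_mask.pixels()
        np.maximum.at(channels["cd68"], (r, c), fg_cd68)

    for ch in channels:
        if config.blur_sigma_px > 0:
            channels[ch] = ndi.gaussian_filter(channels[ch], config.blur_sigma_px)
        if config.noise_sd > 0:
            channels[ch] = channels[ch] + rng.normal(
                0.0, config.noise_sd, size=shape
            ).astype(np.float32)
            np.clip(channels[ch], 0.0, None, out=channels[ch])

    image = ImagePlane(channels=channels, pixel_size_um=px)
    return PhantomScene(image=image, truth_cells=cells, config=config)


def truth_label_masks(scene: PhantomScene) -> Tuple[np.ndarray, np.ndarray]:
    """Full-frame (cells, nuclei) label masks from the ground truth.

    Overlapping cell pixels go to the earlier-placed cell (deterministic).
    """
    shape = scene.image.shape
    cells = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    for i, cell in enumerate(scene.truth_cells, start=1):
        r, c = cell.cell_mask.pixels()
        free = cells[r, c] == 0
        cells[r[free], c[free]] = i
        r, c = cell.nucleus_mask.pixels()
        nuclei[r, c] = i
    return cells, nuclei
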