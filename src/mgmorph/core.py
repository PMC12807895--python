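"""Core containers shared across the pipeline.

Conventions
-----------
* Rasters are indexed ``[row, col]``; pixel ``(0, 0)`` has its *center* at the
  physical origin.  Physical coordinates are ``(x, y) = (col, row) * pixel_size_um``.
* All physical quantities are in micrometres (lengths) or square micrometres
  (areas) unless a name says otherwise.
* Label masks are non-negative integer rasters; 0 is background and labels are
  contiguous positive integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon


class ChannelError(KeyError):
    """A required image channel is missing from an :class:`ImagePlane`."""


@dataclass
class ImagePlane:
    """A 2D multi-channel fluorescence raster with a physical pixel size.

    Parameters
    ----------
    channels:
        Mapping of channel name (e.g. ``"nuclear"``, ``"cd68"``, ``"iba1"``)
        to a 2D float array in arbitrary intensity units (AU).
    pixel_size_um:
        Edge length of one pixel in micrometres.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("ImagePlane needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class RegionAnnotation:
    """A named analysis region as a polygon in micrometre coordinates.

    Holes (e.g. an excluded granule-cell layer) are represented as interior
    rings of the shapely polygon.
    """

    name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.name!r}: polygon is not simple/valid")
        if self.polygon.area <= 0:
            raise ValueError(f"region {self.name!r}: polygon area must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    def to_mask(self, shape: Tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Rasterize: True where the pixel center lies inside the region."""
        import shapely

        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        xs = cols.ravel() * pixel_size_um
        ys = rows.ravel() * pixel_size_um
        inside = shapely.contains_xy(self.polygon, xs, ys)
        return inside.reshape(shape)

    def boundary_mask(self, shape: Tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """1-pixel-wide rasterized boundary of the region."""
        m = self.to_mask(shape, pixel_size_um)
        return m ^ ndi.binary_erosion(m, border_value=0)


@dataclass
class MaskCrop:
    """A boolean mask stored on its bounding box to keep big scenes cheap.

    ``offset`` is the (row, col) of the crop's top-left pixel in the full frame.
    """

    array: np.ndarray
    offset: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.array.sum())

    def to_full(self, shape: Tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.array.shape
        full[r0 : r0 + h, c0 : c0 + w] = self.array
        return full

    def pixels(self) -> Tuple[np.ndarray, np.ndarray]:
        """Absolute (rows, cols) of the True pixels."""
        r, c = np.nonzero(self.array)
        return r + self.offset[0], c + self.offset[1]

    def paste_into(self, full: np.ndarray, value=True) -> None:
        r, c = self.pixels()
        full[r, c] = value

    @classmethod
    def from_full(cls, full: np.ndarray) -> "MaskCrop":
        full = np.asarray(full, dtype=bool)
        if not full.any():
            return cls(np.zeros((0, 0), dtype=bool), (0, 0))
        r, c = np.nonzero(full)
        r0, r1 = r.min(), r.max() + 1
        c0, c1 = c.min(), c.max() + 1
        return cls(full[r0:r1, c0:c1].copy(), (int(r0), int(c0)))


def centroid_px(mask: np.ndarray) -> Tuple[float, float]:
    """Unweighted pixel centroid (row, col) of a boolean mask."""
    r, c = np.nonzero(mask)
    if r.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(r.mean()), float(c.mean())


def relabel_sequential(labels: np.ndarray, keep: "list[int] | None" = None) -> np.ndarray:
    """Relabel a label mask to contiguous 1..K, optionally keeping a subset.

    Order of surviving labels is preserved.
    """
    labels = np.asarray(labels)
    present = [int(v) for v in np.unique(labels) if v > 0]
    if keep is not None:
        keepset = set(int(k) for k in keep)
        present = [v for v in present if v in keepset]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=labels.dtype)
    for new, old in enumerate(present, start=1):
        lut[old] = new
    return lut[labels]
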