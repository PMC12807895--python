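"""File formats: OME-TIFF images, GeoJSON annotations, CSV tables, flat
key=value configs.

Annotation reading targets the QuPath-export GeoJSON dialect: a
FeatureCollection of Polygon features with coordinates in *pixel* units
(converted to μm on ingest using the declared pixel size) and holes as inner
rings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape as shapely_shape

from .core import ImagePlane, RegionAnnotation

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL_NAMES = ("nuclear", "cd68", "iba1")
_SCHEMA_COMMENT = "# mgmorph feature table v1"


# ---------------------------------------------------------------------------
# images


def write_image(path: Union[str, Path], image: ImagePlane) -> None:
    """Write a multi-channel OME-TIFF with pixel-size metadata."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def _pixel_size_from_ome(tf: tifffile.TiffFile) -> Optional[float]:
    if not tf.ome_metadata:
        return None
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
    return float(m.group(1)) if m else None


def _channel_names_from_ome(tf: tifffile.TiffFile, n: int) -> Optional[List[str]]:
    if not tf.ome_metadata:
        return None
    names = re.findall(r'<Channel[^>]*\bName="([^"]+)"', tf.ome_metadata)
    return names if len(names) == n else None


def read_image(
    path: Union[str, Path],
    channel_names: Optional[Sequence[str]] = None,
    pixel_size_um: Optional[float] = None,
) -> ImagePlane:
    """Read a 2–4 channel TIFF/OME-TIFF into an :class:`ImagePlane`.

    Pixel size comes from OME metadata unless ``pixel_size_um`` overrides it
    (the override wins, with a logged warning).  Channel names come from the
    explicit argument, then OME metadata, then the default
    ``(nuclear, cd68, iba1)`` order.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_ome(tf)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 2D multi-channel image, got shape {arr.shape}")
        # accept channel-last layouts
        if arr.shape[0] > 4 and arr.shape[-1] <= 4:
            arr = np.moveaxis(arr, -1, 0)
        n = arr.shape[0]
        if not 1 <= n <= 4:
            raise ValueError(f"{path}: expected 2–4 channels, found {n}; supply a channel mapping")
        if channel_names is None:
            channel_names = _channel_names_from_ome(tf, n) or list(DEFAULT_CHANNEL_NAMES)[:n]
        if len(channel_names) != n:
            raise ValueError(
                f"{path}: {n} channels but {len(channel_names)} channel names"
            )
    if pixel_size_um is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size_um):
            logger.warning(
                "pixel size override %.4g μm wins over metadata %.4g μm",
                pixel_size_um,
                meta_px,
            )
        px = pixel_size_um
    elif meta_px is not None:
        px = meta_px
    else:
        raise ValueError(f"{path}: no pixel size in metadata and no override given")
    channels = {name: arr[i].astype(np.float32) for i, name in enumerate(channel_names)}
    return ImagePlane(channels=channels, pixel_size_um=px)


def write_label_mask(path: Union[str, Path], labels: np.ndarray, pixel_size_um: float) -> None:
    tifffile.imwrite(
        str(path),
        labels.astype(np.int32),
        ome=True,
        metadata={
            "axes": "YX",
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeY": pixel_size_um,
        },
    )


def read_label_mask(path: Union[str, Path]) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(
    path: Union[str, Path], pixel_size_um: float
) -> List[RegionAnnotation]:
    """Read region polygons from a QuPath-dialect GeoJSON FeatureCollection.

    Coordinates are in pixel units and converted to μm; inner rings become
    holes.  Unnamed features are auto-named ``region_<i>`` with a log entry;
    a self-intersecting polygon raises a ValueError naming the feature.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [doc] if doc.get("type") == "Feature" else [])
    regions: List[RegionAnnotation] = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        name = props.get("name")
        if name is None:
            cls = props.get("classification")
            if isinstance(cls, dict):
                name = cls.get("name")
        if name is None:
            name = f"region_{i}"
            logger.info("unnamed annotation feature auto-named %r", name)
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geoms = list(geom.geoms)
        elif geom.geom_type == "Polygon":
            geoms = [geom]
        else:
            raise ValueError(f"feature {name!r}: unsupported geometry {geom.geom_type}")
        for j, g in enumerate(geoms):
            if not g.is_valid:
                raise ValueError(f"feature {name!r}: polygon is self-intersecting")
            scaled = _scale_polygon(g, pixel_size_um)
            suffix = f"_{j}" if len(geoms) > 1 else ""
            regions.append(RegionAnnotation(name=f"{name}{suffix}", polygon=scaled))
    return regions


def _scale_polygon(poly: Polygon, factor: float) -> Polygon:
    ext = [(x * factor, y * factor) for x, y in poly.exterior.coords]
    holes = [
        [(x * factor, y * factor) for x, y in ring.coords] for ring in poly.interiors
    ]
    return Polygon(ext, holes)


def write_annotations(
    path: Union[str, Path], regions: Sequence[RegionAnnotation], pixel_size_um: float
) -> None:
    """Write regions back to QuPath-dialect GeoJSON (pixel-unit coordinates)."""
    feats = []
    for reg in regions:
        scaled = _scale_polygon(reg.polygon, 1.0 / pixel_size_um)
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": reg.name, "objectType": "annotation"},
                "geometry": mapping(scaled),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_cell_outlines(
    path: Union[str, Path],
    cells: np.ndarray,
    pixel_size_um: float,
    properties: Optional[Dict[int, Dict[str, object]]] = None,
) -> None:
    """Cell outlines (one polygon feature per label) as GeoJSON in pixel units."""
    from skimage import measure

    feats = []
    for lbl in range(1, int(cells.max()) + 1):
        mask = cells == lbl
        if not mask.any():
            continue
        contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
        if not contours:
            continue
        poly = max(contours, key=len) - 1.0
        coords = [[float(c), float(r)] for r, c in poly]  # (x, y) = (col, row)
        coords.append(coords[0])
        props: Dict[str, object] = {"cell_id": lbl}
        if properties and lbl in properties:
            props.update(properties[lbl])
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# tables


def write_feature_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    """Per-cell CSV with a version-stamped header comment."""
    with open(path, "w") as fh:
        fh.write(_SCHEMA_COMMENT + "\n")
        table.to_csv(fh, index=False)


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# flat key=value configs


def write_flat_config(path: Union[str, Path], obj) -> None:
    """Serialize a (possibly nested) dataclass to ``key = value`` lines."""
    lines: List[str] = []

    def emit(prefix: str, value) -> None:
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            for f in dataclasses.fields(value):
                emit(f"{prefix}.{f.name}", getattr(value, f.name))
        elif isinstance(value, dict):
            lines.append(f"{prefix} = {json.dumps(value)}")
        elif isinstance(value, (list, tuple)):
            lines.append(f"{prefix} = {json.dumps(list(value))}")
        elif value is None:
            lines.append(f"{prefix} =")
        else:
            lines.append(f"{prefix} = {value}")

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            emit(f.name, getattr(obj, f.name))
    else:
        for k, v in dict(obj).items():
            emit(k, v)
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path: Union[str, Path]) -> Dict[str, str]:
    """Parse ``key = value`` lines (comments with ``#``, blank lines ignored)."""
    out: Dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
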