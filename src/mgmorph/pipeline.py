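"""End-to-end orchestration: image + region in, per-cell feature table out.

``measure_cells`` is the library-level workhorse (label masks + channels to a
feature table); ``run_pipeline`` wraps the whole published workflow order —
pixel classification, nucleus segmentation and filtering, assembly, watershed
separation, QC, per-cell morphometry and Sholl, spatial statistics, reactive
calling, summaries — reading and writing files and a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import io as mio
from .analysis import classify_reactive, summarize_by_region
from .core import ImagePlane, RegionAnnotation
from .morphometry import compute_cell_features
from .segmentation import SegmentationParams, segment_cells
from .sholl import sholl_metrics, sholl_profile
from .spatial import (
    clump_neighbors,
    delaunay_mean_neighbor_distance,
    nearest_neighbor_distance,
)

logger = logging.getLogger(__name__)

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of the full pipeline.

    Defaults encode the standard parameterization: 0.2 μm² detection floor,
    30% Iba1⁺ nucleus fraction, 100 μm collection radius, 3 px soma dilation,
    1000 AU CD68 threshold, 0.25/50 μm Sholl sampling, 250/25 μm Delaunay
    cutoffs, the 35% / BI 1 / 25 μm reactive rule, and 5/50 μm² QC floors.
    """

    image_path: str = ""
    region_path: str = ""
    nuclei_path: str = ""  # optional precomputed nucleus label mask
    output_dir: str = "mgmorph_out"
    region_name: str = ""  # empty: first annotation in the file
    pixel_size_um: float = 0.0  # 0: take from image metadata
    channel_nuclear: str = "nuclear"
    channel_cd68: str = "cd68"
    channel_iba1: str = "iba1"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    soma_dilation_px: int = 3
    cd68_threshold_au: float = 1000.0
    sholl_step_um: float = 0.25
    sholl_max_radius_um: float = 50.0
    sri_denominator: str = "n_branches"  # or "n_primary"
    delaunay_max_um: float = 250.0
    clump_max_um: float = 25.0
    reactive_cd68_min_pct: float = 35.0
    reactive_bi_min: int = 1
    animal_id: str = "animal0"
    genotype: str = "Ctrl"
    sex: str = "F"
    rng_seed: int = 0
    write_sholl_profiles: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        flat = mio.read_flat_config(path)
        return cls.from_flat(flat)

    @classmethod
    def from_flat(cls, flat: Dict[str, str]) -> "PipelineConfig":
        cfg = cls()
        seg_fields = {f.name: f for f in dataclasses.fields(SegmentationParams)}
        top_fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in flat.items():
            if key.startswith("segmentation."):
                name = key.split(".", 1)[1]
                if name not in seg_fields:
                    raise ValueError(f"unknown config key {key!r}")
                setattr(cfg.segmentation, name, _coerce(raw, seg_fields[name].type))
            elif key in top_fields and key != "segmentation":
                setattr(cfg, key, _coerce(raw, top_fields[key].type))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    def to_file(self, path) -> None:
        mio.write_flat_config(path, self)


def _coerce(raw: str, annotation) -> object:
    raw = raw.strip()
    text = annotation if isinstance(annotation, str) else getattr(annotation, "__name__", str(annotation))
    if raw == "" or raw.lower() == "none":
        return None if "Optional" in text or raw.lower() == "none" else ""
    if "bool" in text:
        return raw.lower() in ("1", "true", "yes")
    if "int" in text and "float" not in text:
        return int(raw)
    if "float" in text:
        return float(raw)
    return raw


# ---------------------------------------------------------------------------


def measure_cells(
    image: ImagePlane,
    cells: np.ndarray,
    nuclei: np.ndarray,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Per-cell feature table for matched (cells, nuclei) label masks.

    Includes morphometry, skeleton, Sholl summary and spatial columns, plus
    the reactive flag and metadata columns from the config.
    """
    config = config or PipelineConfig()
    px = image.pixel_size_um
    iba1 = image.channel(config.channel_iba1)
    cd68 = image.channel(config.channel_cd68)
    n = int(cells.max())
    records = []
    cell_centroids = []
    nucleus_centroids = []
    slices = ndi.find_objects(cells, max_label=n)
    for lbl in range(1, n + 1):
        sl = slices[lbl - 1]
        if sl is None:
            continue
        pad = 6
        r0 = max(sl[0].start - pad, 0)
        c0 = max(sl[1].start - pad, 0)
        r1 = min(sl[0].stop + pad, cells.shape[0])
        c1 = min(sl[1].stop + pad, cells.shape[1])
        window = (slice(r0, r1), slice(c0, c1))
        cell_mask = cells[window] == lbl
        nucleus_mask = nuclei[window] == lbl
        if not nucleus_mask.any():
            logger.warning("cell %d has no matching nucleus; skipped", lbl)
            continue
        feats = compute_cell_features(
            lbl,
            cell_mask,
            nucleus_mask,
            iba1[window],
            cd68[window],
            px,
            cd68_threshold_au=config.cd68_threshold_au,
            soma_dilation_px=config.soma_dilation_px,
        )
        profile = sholl_profile(
            cell_mask,
            nucleus_mask,
            px,
            step_um=config.sholl_step_um,
            max_radius_um=config.sholl_max_radius_um,
        )
        denom = (
            feats.n_branches
            if config.sri_denominator == "n_branches"
            else int(profile.intersections[0])
        )
        sm = sholl_metrics(profile, denom)
        feats.critical_value = sm["critical_value"]
        feats.critical_radius_um = sm["critical_radius_um"]
        feats.n_primary = sm["n_primary"]
        feats.sri = sm["sri"]
        feats.region = config.region_name or "region_0"
        feats.animal_id = config.animal_id
        feats.genotype = config.genotype
        feats.sex = config.sex
        records.append(feats.to_dict())

        cr, cc = np.nonzero(cell_mask)
        cell_centroids.append(((cc.mean() + c0) * px, (cr.mean() + r0) * px))
        nr, nc = np.nonzero(nucleus_mask)
        nucleus_centroids.append(((nc.mean() + c0) * px, (nr.mean() + r0) * px))

    table = pd.DataFrame.from_records(records)
    if table.empty:
        return table
    cell_xy = np.array(cell_centroids)
    nuc_xy = np.array(nucleus_centroids)
    table["centroid_x_um"] = cell_xy[:, 0]
    table["centroid_y_um"] = cell_xy[:, 1]
    table["delaunay_mean_neighbor_um"] = delaunay_mean_neighbor_distance(
        cell_xy, config.delaunay_max_um
    )
    min_dist, _flags = clump_neighbors(nuc_xy, config.clump_max_um)
    table["min_nucleus_neighbor_um"] = min_dist
    table["nnd_um"] = nearest_neighbor_distance(cell_xy)
    table["reactive"] = classify_reactive(
        table,
        cd68_min_pct=config.reactive_cd68_min_pct,
        bi_min=config.reactive_bi_min,
        clump_um=config.clump_max_um,
    )
    return table


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the full workflow from files per the config; returns the
    per-cell table and writes all outputs plus a run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    stage("read_image")
    image = mio.read_image(
        config.image_path,
        channel_names=None,
        pixel_size_um=config.pixel_size_um or None,
    )
    # remap channels if custom names were configured
    rename = {
        config.channel_nuclear: "nuclear",
        config.channel_cd68: "cd68",
        config.channel_iba1: "iba1",
    }
    image = ImagePlane(
        channels={rename.get(k, k): v for k, v in image.channels.items()},
        pixel_size_um=image.pixel_size_um,
    )

    stage("read_annotations")
    regions = mio.read_annotations(config.region_path, image.pixel_size_um)
    if config.region_name:
        matches = [r for r in regions if r.name == config.region_name]
        if not matches:
            raise ValueError(f"region {config.region_name!r} not in annotation file")
        region = matches[0]
    else:
        region = regions[0]

    external = mio.read_label_mask(config.nuclei_path) if config.nuclei_path else None

    stage("segmentation")
    cells, nuclei = segment_cells(
        image, region, config.segmentation, external_nuclei=external
    )

    stage("morphometry")
    cfg = dataclasses.replace(config, region_name=config.region_name or region.name)
    table = measure_cells(image, cells, nuclei, cfg)

    stage("outputs")
    mio.write_feature_table(out / "cells.csv", table)
    mio.write_label_mask(out / "cell_labels.ome.tiff", cells, image.pixel_size_um)
    mio.write_label_mask(out / "nucleus_labels.ome.tiff", nuclei, image.pixel_size_um)
    if not table.empty:
        summary = summarize_by_region(table)
        mio.write_feature_table(out / "animal_summary.csv", summary)
        reactive_ids = table.loc[table["reactive"].astype(bool), "cell_id"]
        mio.write_cell_outlines(
            out / "reactive_cells.geojson",
            np.where(np.isin(cells, list(reactive_ids)), cells, 0),
            image.pixel_size_um,
            properties={int(i): {"reactive": True} for i in reactive_ids},
        )
    manifest = {
        "package_version": PACKAGE_VERSION,
        "seed": config.rng_seed,
        "n_cells": int(table.shape[0]),
        "region": region.name,
        "config": _dataclass_to_jsonable(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def _dataclass_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _dataclass_to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
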