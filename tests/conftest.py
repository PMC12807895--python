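"""Shared fixtures: analytic shapes and seeded phantom scenes.

The end-to-end scene is session-scoped (rendered, segmented and measured
once) because several modules assert different properties of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box
from skimage.draw import disk as draw_disk

from mgmorph.core import RegionAnnotation
from mgmorph.phantoms import SceneConfig, render_scene
from mgmorph.pipeline import measure_cells
from mgmorph.segmentation import segment_cells

PX = 0.172  # μm, the acquisition pixel size emulated throughout


def disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


@pytest.fixture(scope="session")
def e2e_scene():
    """Noiseless 30-cell scene: 25 ramified + 5 chain-clustered reactive."""
    config = SceneConfig(
        width_px=3256,
        height_px=3256,
        n_cells_per_phenotype={"ramified": 25, "reactive": 5},
        cluster_center_um=(90.0, 90.0),
        noise_sd=0.0,
        blur_sigma_px=0.0,
        rng_seed=7,
    )
    return render_scene(config)


@pytest.fixture(scope="session")
def e2e_region(e2e_scene):
    w = (e2e_scene.config.width_px - 1) * e2e_scene.config.pixel_size_um
    return RegionAnnotation("hippocampus", box(-1.0, -1.0, w + 1.0, w + 1.0))


@pytest.fixture(scope="session")
def e2e_segmentation(e2e_scene, e2e_region):
    cells, nuclei = segment_cells(e2e_scene.image, e2e_region)
    return cells, nuclei


@pytest.fixture(scope="session")
def e2e_table(e2e_scene, e2e_segmentation):
    cells, nuclei = e2e_segmentation
    return measure_cells(e2e_scene.image, cells, nuclei)


@pytest.fixture(scope="session")
def e2e_matched(e2e_scene, e2e_segmentation):
    """Map each truth cell to its segmented label via the nucleus centroid."""
    cells, nuclei = e2e_segmentation
    pairs = []
    for tc in e2e_scene.truth_cells:
        r, c = tc.nucleus_mask.pixels()
        lbl = int(nuclei[int(r.mean()), int(c.mean())])
        pairs.append((tc, lbl))
    return pairs


@pytest.fixture(scope="session")
def small_scene():
    """Small noiseless scene for segmentation unit tests (6 ramified cells)."""
    config = SceneConfig(
        width_px=1600,
        height_px=1600,
        n_cells_per_phenotype={"ramified": 6},
        noise_sd=0.0,
        blur_sigma_px=0.0,
        rng_seed=3,
    )
    return render_scene(config)
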