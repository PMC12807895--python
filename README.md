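# mgmorph

Microglial morphometry for 2D multi-channel fluorescence images.

Microglia report their activation state in their shape: surveillant cells are
small-bodied with fine, highly ramified arbors; primed cells hyper-ramify;
reactive cells retract and thicken their processes, upregulate the
phagolysosomal marker CD68, and cluster together. `mgmorph` turns a
three-channel image (nuclear stain, CD68, Iba1) plus a region annotation into
a per-cell feature table covering shape, skeleton, Sholl, intensity and
spatial statistics, and calls reactive cells with transparent thresholds — the
kind of semi-automated pipeline a histology lab runs over whole hippocampal
sections with thousands of cells.

It is aimed at neuroimmunology groups quantifying early microglial remodeling
(e.g. in amyloidosis models), and at image-analysis developers who need a
ground-truthed benchmark: the built-in phantom generator renders synthetic
scenes of branching cells with *exact* known morphology, so every stage of
the pipeline is testable without real data.

## Method

Segmentation is nucleus-anchored:

1. an Iba1 process mask (configurable classical pixel classifier stand-in:
   Gaussian smooth → threshold → 0.2 μm² size floor; external masks accepted),
2. nucleus segmentation on the nuclear channel (marker-controlled watershed;
   external label masks, e.g. from a deep-learning segmenter, accepted),
3. nuclei ≥ 30% Iba1⁺ by area are microglial; others are dropped,
4. per nucleus, Iba1 detections within 100 μm are collected, gaps closed
   morphologically, and the component contiguous with the nucleus becomes a
   candidate cell,
5. overlapping candidates are split by marker-controlled watershed over
   geodesic distance from the nucleus centroids,
6. QC removes cells whose nucleus touches the region boundary or with
   nucleus area < 5 μm² or cell area < 50 μm².

Per cell, with pixel size s (μm) and the usual definitions:

* area A, perimeter P (traced boundary polygon), circularity = 4πA/P²,
  solidity = A/A_hull, convexity = P_hull/P, aspect ratio = Feret_max/Feret_min
  (rotating calipers on the boundary hull);
* skeleton analysis after deleting the soma (nucleus ⊕ 3 px): total branch
  length, branch points (junctions), end points, branch count;
  branching index BI = junction count;
  branch thickness = (A − A_nucleus) / skeleton length;
* Sholl profile: circles every 0.25 μm from the nucleus-equivalent radius out
  to 50 μm; critical value/radius, Schoenen ramification index
  SRI = critical value / branch count;
* mean Iba1 intensity; CD68⁺ area fraction (> 1000 AU, strict);
* nuclear offset = ‖cell centroid − nucleus centroid‖;
* Delaunay mean neighbor distance (250 μm cutoff), nucleus clump distance
  (25 μm cutoff), nearest-neighbor distance, density per mm².

A cell is **reactive** iff CD68⁺ area ≥ 35%, BI ≥ 1, and its nucleus lies
< 25 μm from another nucleus.

## Worked example

Render a small noiseless phantom scene (8 ramified + 4 clustered reactive
cells), segment it, and summarize:

```python
import mgmorph as mg
from mgmorph.core import RegionAnnotation
from mgmorph.phantoms import SceneConfig, render_scene
from shapely.geometry import box

config = SceneConfig(
    width_px=2200, height_px=2200,
    n_cells_per_phenotype={"ramified": 8, "reactive": 4},
    cluster_center_um=(80.0, 80.0),
    noise_sd=0.0, blur_sigma_px=0.0, rng_seed=42,
)
scene = render_scene(config)
w = (config.width_px - 1) * config.pixel_size_um
region = RegionAnnotation("hippocampus", box(-1, -1, w + 1, w + 1))
cells, nuclei = mg.segment_cells(scene.image, region)
table = mg.measure_cells(scene.image, cells, nuclei)

print(f"segmented {int(cells.max())} cells "
      f"({mg.density_per_mm2(int(cells.max()), region):.0f} cells/mm^2)")
print(f"reactive cells called: {int(table['reactive'].sum())}")
cols = ["area_um2", "circularity", "skeleton_length_um", "branching_index",
        "cd68_area_fraction", "min_nucleus_neighbor_um"]
print(table.groupby("reactive")[cols].median().round(2).to_string())
```

Output:

```
segmented 12 cells (83 cells/mm^2)
reactive cells called: 4
          area_um2  circularity  skeleton_length_um  branching_index  cd68_area_fraction  min_nucleus_neighbor_um
reactive
False       152.56         0.02              152.97              8.5                0.10                      NaN
True         82.58         0.18               26.85              2.0                0.45                    18.24
```

All 12 truth cells are recovered and exactly the 4 reactive-phenotype cells
are called reactive. The medians show the expected contrast: reactive cells
are smaller and rounder, with short thick processes, ~45% CD68⁺ area and a
clustered nucleus; ramified cells have long arbors (~153 μm skeleton), many
branch points and low CD68, and are too isolated for a clump distance (NaN).

The same workflow is available from the shell:

```bash
mgmorph simulate scene_dir --n-ramified 8 --n-reactive 4 --noise-sd 0 --blur-sigma-px 0
mgmorph segment scene_dir/scene.ome.tiff regions.geojson --out-dir out
mgmorph measure scene_dir/scene.ome.tiff out/cell_labels.ome.tiff out/nucleus_labels.ome.tiff
mgmorph report cells.csv
```

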