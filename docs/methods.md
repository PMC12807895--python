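# Methods

This note documents the models, conventions and numerical choices behind
`mgmorph`, in the spirit of a methods section a maintainer can audit.

## The phantom model

Synthetic cells are 2D polyline trees stroked at constant width. A cell is a
soma disk plus `n_primary_branches` processes; each branch at depth *d* has
length `segment_length_um · length_decay^d`, built from ~1 μm steps whose
heading performs a random walk with standard deviation `tortuosity` per step.
A branch below `branch_depth − 1` spawns up to `children_per_branch` children
(each realized with probability `child_prob`) fanned around the parent
heading by ±`fork_half_angle`. Because the tree is explicit, the generator
records exact ground truth per cell: primary count, junction count (nodes
where ≥ 2 children attach), endpoint count (leaves), and the analytic
skeleton length (sum of polyline lengths).

**Self-avoidance.** Branch growth rejects (up to 5 jittered angles, then
drops the child) any polyline that comes within a clearance of
`max(1.8, thickness + 1.2)` μm of another branch, or of itself beyond a 2 μm
fork-adjacency zone. This is what makes the recorded topology *true of the
raster*: without it, touching strokes merge and create junctions the tree
never had. Counts always describe the realized (post-rejection) tree.

**Nucleus.** An ellipse with semi-axes `max(0.75·r_s, r_s − 0.15)` and
`max(0.60·r_s, r_s − 0.35)` μm for soma radius `r_s`, randomly oriented.
Microglia carry scant perinuclear cytoplasm, so the nucleus nearly fills the
soma; numerically this also guarantees the standard soma deletion (nucleus
dilated by 3 px) covers the soma disk, leaving no annulus to skeletonize.

**CD68.** Granules are ~0.45 μm disks dropped uniformly inside the cell mask
until coverage reaches the preset fraction; achieved coverage is recorded and
lands within ±5 percentage points of the target.

**Channels and noise.** Nuclear/CD68/Iba1 foregrounds default to
1500/2000/2000 AU over a 100 AU background (matching the convention in which
CD68 positivity is an absolute 1000 AU cut). The scene applies Gaussian blur
(`blur_sigma_px`, default 1) then additive Gaussian noise (`noise_sd`,
default 20 AU) — emulating an already-deconvolved widefield projection; no
PSF, photobleaching or 3D structure is simulated. Ground truth is recorded
before degradation. A scene is a pure function of its config (one RNG seeded
by `rng_seed`), so identical configs give bit-identical images.

**Phenotype presets.** The four presets encode the activation continuum as
used in the morphometric literature; the geometry numbers are conventions of
this generator, chosen so the qualitative contrasts hold (hyper-ramified
strictly exceeds ramified in branch count × depth and segment length;
amoeboid is soma-only with the thickest stroke; reactive carries ≥ 35% CD68
and deterministic forks so that every reactive-preset cell actually satisfies
the branching clause of the reactive definition).

**Placement.** Non-clustered cells are placed uniformly with a 60 μm minimum
separation — microglia tile the parenchyma in largely non-overlapping
territories, and 60 μm keeps two full ramified arbors (reach ≈ 28 μm)
disjoint. Clustered (reactive) cells are placed inside a disk
(`cluster_radius_um`, default 25) as a loose chain: ≥ 15 μm apart (somas and
proximal arbors disjoint) but each within 24 μm of another clustered cell, so
every member satisfies the < 25 μm nucleus-clump rule by construction.
Placement is retry-based (budget 100); a dead-ended cluster layout is
discarded and restarted rather than failing on an unlucky draw.

What passing tests on phantoms do *not* show: robustness to uneven
illumination, anisotropic PSF blur, autofluorescence, section artifacts, or
the morphological ambiguity of real tissue. The phantoms validate the
measurement chain, not the biology.

## Segmentation

The published workflow this package automates used a trained pixel classifier
and a deep-learning nucleus segmenter; neither ships weights, so both stages
are pluggable interfaces with classical defaults behind the same contracts.

* **Iba1 classification**: Gaussian smooth (σ = 1 px) → threshold → remove
  detections < 0.2 μm². The default threshold (1050 AU) is the half-maximum
  between the typical background (100 AU) and process plateau (2000 AU);
  half-height thresholding preserves object width under smoothing, which the
  mask-recovery properties require of any faithful stand-in. Any external
  binary mask can be substituted.
* **Nuclei**: smooth → Otsu (or fixed) threshold → fill holes →
  distance-transform peaks (minimum separation 2 μm) → watershed. External
  label masks are validated (shape, non-negative labels) and relabeled.
* **Assembly**: per microglial nucleus (≥ 30% Iba1⁺ by area, inclusive),
  detections within 100 μm of the nucleus *centroid* are collected, closed
  with a 2 px radius (exposed; the source protocol does not state a value),
  and the component contiguous with the nucleus is kept and unioned with the
  nucleus. Unanchored Iba1 objects are discarded.
* **Separation**: pixels claimed by several candidates go to the anchor whose
  nucleus centroid is geodesically closest *within that candidate's mask*
  (uniform-cost `MCP_Geometric`); ties break toward the lower label for
  determinism. Nuclei are force-assigned to their own cells, and a
  reconnection pass reassigns any stray component to the adjacent cell it
  touches most, so cells stay connected and the union of pixels is conserved
  exactly.
* **QC**: strict `<` on both area floors (5 μm² nucleus, 50 μm² cell), so
  boundary values survive; a nucleus intersecting the rasterized 1 px region
  boundary, or lying entirely outside the region, removes the cell. The
  filter is idempotent and relabels cells and nuclei to matching 1..K.

Coordinates: pixel indices are 0-based; physical coordinates put the origin
at the center of pixel (0, 0); polygons are in μm (annotation files in the
QuPath GeoJSON dialect carry pixel units and are scaled on ingest).

## Morphometry

* **Perimeter** is the length of the marching-squares boundary polygon
  (0.5 level) after a 5-point circular moving average. Raw marching-squares
  length overestimates smooth boundaries (digitized disk circularity ≈ 0.91);
  the smoothing brings a 50 px-radius disk to circularity 0.994 while a 40 px
  square stays at 0.824 (π/4 = 0.785). Convexity can exceed 1 by up to ~3% on
  shapes with sharp corners (the hull perimeter is unsmoothed); tests treat
  1 + 0.03 as the digitization tolerance.
* **Hull and Feret** features come from the convex hull of the (unsmoothed)
  boundary polygon vertices: hull area by shoelace, maximum Feret by pairwise
  scan over hull vertices, minimum Feret by rotating calipers over hull edge
  normals. Hull area is floored at the pixel area so solidity ≤ 1.
  Degenerate (collinear) boundaries fall back to pixel-corner points.
* **Skeleton**: processes = cell minus (nucleus ⊕ disk(3 px)); thinned with
  `skimage.skeletonize`; pixel graph with 4-steps of weight 1 and diagonal
  steps of weight √2, dropping diagonals that shortcut an existing
  4-connected corner (the classical skeleton-length convention). Thinning
  artifacts scale with stroke width, so the half-width w (median distance
  transform under the skeleton) calibrates two cleanups: terminal spurs
  shorter than `max(2, 1.7w + 1)` px are pruned ("fishtails" at blunt tips),
  and junction pixel clusters within `max(3, 2w)` px merge into one branch
  point (a thick fork thins into two nearby 3-way pixels). Endpoints are
  degree-1 pixels not adjacent (within ⌈w⌉ + 2 px) to the deleted soma —
  those are branch roots, not tips. Branches are maximal junction-free paths.
  On noiseless phantoms these choices recover junction counts exactly on
  isolated cells of all four presets (119/120 across 30 seeds × 4 presets;
  the one residual was a hyper-ramified fork fusion) and skeleton length with
  Pearson r > 0.99.
* **Branching index** is the skeleton junction count; the reactive rule
  "BI ≥ 1" then reads "at least one branch point". (A Sholl-derived
  alternative exists in the literature; the skeleton definition is the one
  used here throughout.)
* **Intensity**: CD68 positivity is strict (`> 1000 AU`); the CD68 area
  fraction is stored in [0, 1] and compared as a percentage in the reactive
  rule. Iba1 is the plain mean over cell pixels.

## Sholl

Circles start at the nucleus equivalent-disk radius (the non-circular
nucleus's "edge") and step 0.25 μm out to 50 μm. Each circle is sampled at
≤ 0.5 px arc spacing on the nucleus-excluded cell mask; an optional
`soma_dilation_px` reproduces the skeleton-style soma deletion instead.
Intersections are circular runs of in-mask samples; runs and gaps narrower
than 2 px are rasterization noise (the circle grazing a ragged pixel
boundary) and are closed/dropped — features thinner than 2 px are below the
counting resolution. The critical value is the maximum count, attained first
at the critical radius; `n_primary` is the count at the first radius (only
meaningful for thin-armed shapes — on a filled soma the first circles lie
inside the cell body); SRI = critical value / branch count, with the skeleton
branch count as the default denominator and the primary count selectable.
Null conventions: an all-zero profile has no critical radius and no SRI; so
does a cell with zero branches.

## Spatial statistics

One Delaunay triangulation of the centroids; edges beyond the cutoff
(250 μm for cell neighbor means, 25 μm for nucleus clumps) are discarded
per-edge, not re-triangulated. The clump flag is strict (< 25 μm). Exact
duplicate points are perturbed deterministically by < 10⁻⁶ μm; collinear or
sub-triangulation-size point sets fall back to the all-pairs graph under the
same cutoffs (logged). Fewer than 3 points yield all-null neighbor means.
Density divides the cell count by the polygon area (holes subtracted).

## Analysis

Reactive calling is the three-threshold conjunction with the boundary
conventions stated above; a cell with no neighbor distance is never reactive.
Decile partitioning stable-sorts by the chosen feature and splits into
contiguous groups of ⌈N/n⌉ (first N mod n groups) then ⌊N/n⌋ — a 10,490-row
table gives ten groups of exactly 1,049. Region summaries take per-animal,
per-region medians of all numeric features. The reactive-vs-homeostatic
profile reports medians, quartiles and median deltas per feature; hypothesis
testing (ANOVA, post-hoc tests, outlier pruning) is deliberately out of
scope — the tables are exported for external statistics packages.

## Problem sizes

The test suite's end-to-end scene holds 30 cells (25 ramified + 5 clustered
reactive) on a 3256² px canvas at 0.172 μm/px; the acceptance script scales
the same conditions to 100 cells on 5400² px. Both are noiseless
(`noise_sd = 0, blur_sigma_px = 0`): the recovery criteria characterize the
measurement chain's agreement with ground truth, and noise robustness is a
separate question the defaults (blur σ = 1 px, noise 20 AU) let a user probe.

## Known limitations

* 2D only; no 3D stacks, no PSF or deconvolution modeling.
* The classical classifier stand-ins are contracts, not re-implementations of
  trained models; on real tissue a trained classifier (or external masks)
  should be plugged in.
* Junction recovery can overcount by one on extremely dense arbors when two
  forks fuse within a stroke width.
* Mask-based Sholl `n_primary` is unreliable on filled somas (see above).
* Watershed separation assigns contested arbor territory by geodesic
  proximity; heavily interpenetrating cells (pathological clusters tighter
  than ~15 μm) lose distal branches to their neighbors, which depresses
  per-cell branching metrics in exactly those clusters.
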