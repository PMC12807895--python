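"""Segmentation chain: pixel classification, nuclei, assembly, watershed
separation, QC — on constructed fixtures and noiseless phantoms."""

import numpy as np
import pytest
from shapely.geometry import box
from skimage.draw import disk as draw_disk

from mgmorph.core import ImagePlane, MaskCrop, RegionAnnotation
from mgmorph.segmentation import (
    CellCandidate,
    SegmentationParams,
    apply_qc_filters,
    assemble_microglia,
    classify_iba1_pixels,
    filter_iba1_positive_nuclei,
    segment_nuclei,
    separate_overlapping,
)

PX = 0.172


def disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def image_from(iba1=None, nuclear=None, cd68=None, px=PX):
    shape = next(a.shape for a in (iba1, nuclear, cd68) if a is not None)
    channels = {}
    channels["iba1"] = iba1 if iba1 is not None else np.full(shape, 100.0)
    channels["nuclear"] = nuclear if nuclear is not None else np.full(shape, 100.0)
    channels["cd68"] = cd68 if cd68 is not None else np.full(shape, 100.0)
    return ImagePlane(channels={k: v.astype(np.float32) for k, v in channels.items()},
                      pixel_size_um=px)


class TestClassifyIba1:
    def test_uniform_background_gives_empty_mask(self):
        img = image_from(iba1=np.full((128, 128), 100.0))
        assert not classify_iba1_pixels(img, SegmentationParams()).any()

    def test_phantom_mask_covers_truth(self, small_scene):
        """Noiseless scene: mask catches >= 99% of true cell pixels and
        <= 1% of background pixels."""
        mask = classify_iba1_pixels(small_scene.image, SegmentationParams())
        truth = np.zeros(small_scene.image.shape, dtype=bool)
        for tc in small_scene.truth_cells:
            tc.cell_mask.paste_into(truth)
        assert (mask & truth).sum() / truth.sum() >= 0.99
        assert (mask & ~truth).sum() / (~truth).sum() <= 0.01

    def test_detection_below_size_floor_removed(self):
        """A 5-px detection is 0.148 μm² (< 0.2 μm² floor) and is dropped; a
        7-px one (0.207 μm²) survives."""
        iba1 = np.full((64, 64), 100.0)
        iba1[10, 10:15] = 5000.0  # 5 px
        iba1[40, 30:37] = 5000.0  # 7 px
        params = SegmentationParams(iba1_smooth_sigma_px=0.0)
        mask = classify_iba1_pixels(image_from(iba1=iba1), params)
        assert not mask[10, 10:15].any()
        assert mask[40, 30:37].all()

    def test_missing_channel_is_configuration_error(self):
        from mgmorph.core import ChannelError

        img = ImagePlane(channels={"nuclear": np.zeros((8, 8))}, pixel_size_um=PX)
        with pytest.raises(ChannelError):
            classify_iba1_pixels(img, SegmentationParams())


class TestSegmentNuclei:
    def test_two_disjoint_nuclei_found_with_subpixel_centroids(self):
        nuclear = np.full((200, 200), 100.0)
        for center in ((60, 60), (140, 150)):
            rr, cc = draw_disk(center, 15, shape=(200, 200))
            nuclear[rr, cc] = 1500.0
        labels = segment_nuclei(image_from(nuclear=nuclear), SegmentationParams())
        assert labels.max() == 2
        found = []
        for lbl in (1, 2):
            r, c = np.nonzero(labels == lbl)
            found.append((r.mean(), c.mean()))
        found.sort()
        for (fr, fc), (tr, tc) in zip(found, [(60, 60), (140, 150)]):
            assert abs(fr - tr) < 1 and abs(fc - tc) < 1

    def test_blank_channel_gives_empty_mask(self):
        labels = segment_nuclei(image_from(nuclear=np.full((64, 64), 100.0)),
                                SegmentationParams())
        assert labels.max() == 0

    def test_fused_dumbbell_is_split_by_distance_peaks(self):
        nuclear = np.full((120, 200), 100.0)
        for center in ((60, 80), (60, 112)):
            rr, cc = draw_disk(center, 20, shape=(120, 200))
            nuclear[rr, cc] = 1500.0
        labels = segment_nuclei(image_from(nuclear=nuclear), SegmentationParams())
        assert labels.max() == 2

    def test_external_mask_passthrough_and_validation(self):
        img = image_from(nuclear=np.full((64, 64), 100.0))
        ext = np.zeros((64, 64), dtype=np.int32)
        ext[10:20, 10:20] = 5  # sparse labels get compacted
        out = segment_nuclei(img, SegmentationParams(), external_mask=ext)
        assert out.max() == 1 and (out[10:20, 10:20] == 1).all()
        with pytest.raises(ValueError):
            segment_nuclei(img, SegmentationParams(),
                           external_mask=np.zeros((32, 32), dtype=np.int32))


class TestIba1PositiveNuclei:
    def test_boundary_inclusive_at_30_percent(self):
        nuclei = np.zeros((40, 40), dtype=np.int32)
        nuclei[0:10, 0:10] = 1  # 100 px
        iba1 = np.zeros((40, 40), dtype=bool)
        iba1[0:3, 0:10] = True  # exactly 30 px
        assert filter_iba1_positive_nuclei(nuclei, iba1, 0.30).max() == 1

    def test_29_percent_removed(self):
        nuclei = np.zeros((40, 40), dtype=np.int32)
        nuclei[0:10, 0:10] = 1
        iba1 = np.zeros((40, 40), dtype=bool)
        iba1.flat[:0] = True
        iba1[0:2, 0:10] = True
        iba1[2, 0:9] = True  # 29 px
        assert filter_iba1_positive_nuclei(nuclei, iba1, 0.30).max() == 0

    def test_random_masks_match_counting_oracle(self):
        rng = np.random.default_rng(0)
        nuclei = np.zeros((300, 300), dtype=np.int32)
        for lbl in range(1, 51):
            r, c = rng.integers(10, 290, 2)
            rr, cc = draw_disk((r, c), 6, shape=(300, 300))
            nuclei[rr, cc] = lbl  # later labels may overwrite; that's fine
        iba1 = rng.random((300, 300)) < 0.4
        kept = filter_iba1_positive_nuclei(nuclei, iba1, 0.30)
        # oracle: per-label pixel counting
        expected = []
        for lbl in range(1, 51):
            sel = nuclei == lbl
            if sel.any() and iba1[sel].sum() / sel.sum() >= 0.30:
                expected.append(lbl)
        assert kept.max() == len(expected)
        # order preserved: k-th kept label corresponds to k-th expected
        for new, old in enumerate(expected, start=1):
            assert (kept[nuclei == old] == new).all()


class TestAssemble:
    def test_nucleus_inside_blob_yields_blob_union_nucleus(self):
        shape = (200, 200)
        blob = disk_mask(shape, (100, 100), 40)
        nuclei = np.where(disk_mask(shape, (100, 100), 10), 1, 0).astype(np.int32)
        cands = assemble_microglia(blob, nuclei, SegmentationParams(), PX)
        assert len(cands) == 1
        got = cands[0].mask.to_full(shape)
        assert (got == (blob | (nuclei > 0))).all()

    def test_far_blob_not_collected(self):
        """An Iba1 object 200 μm from any nucleus is absent from every
        candidate."""
        shape = (2000, 2000)
        blob_near = disk_mask(shape, (600, 600), 30)
        far = disk_mask(shape, (600, 600 + int(200 / PX)), 30)
        nuclei = np.where(disk_mask(shape, (600, 600), 10), 1, 0).astype(np.int32)
        cands = assemble_microglia(blob_near | far, nuclei, SegmentationParams(), PX)
        union = np.zeros(shape, dtype=bool)
        for c in cands:
            c.mask.paste_into(union)
        assert not (union & far).any()
        assert (union & blob_near).sum() == blob_near.sum()

    def test_one_pixel_gap_closed(self):
        shape = (100, 160)
        left = np.zeros(shape, dtype=bool)
        left[40:60, 20:80] = True
        right = np.zeros(shape, dtype=bool)
        right[40:60, 81:140] = True  # 1-px gap at col 80
        nuclei = np.where(disk_mask(shape, (50, 40), 8), 1, 0).astype(np.int32)
        params = SegmentationParams(closing_radius_px=2)
        cands = assemble_microglia(left | right, nuclei, params, PX)
        got = cands[0].mask.to_full(shape)
        assert got[40:60, 100:140].any()  # right side joined across the gap

    def test_isolated_nucleus_yields_nucleus_only_candidate(self):
        shape = (300, 300)
        nuclei = np.where(disk_mask(shape, (150, 150), 10), 1, 0).astype(np.int32)
        cands = assemble_microglia(np.zeros(shape, bool), nuclei, SegmentationParams(), PX)
        assert len(cands) == 1
        assert cands[0].mask.area_px == (nuclei > 0).sum()


class TestSeparateOverlapping:
    def _candidate(self, mask, lbl, centroid):
        return CellCandidate(anchor_label=lbl, mask=MaskCrop.from_full(mask),
                             nucleus_centroid_px=centroid)

    def test_disjoint_candidates_unchanged(self):
        shape = (120, 240)
        a = disk_mask(shape, (60, 60), 25)
        b = disk_mask(shape, (60, 180), 25)
        nuclei = np.where(disk_mask(shape, (60, 60), 6), 1, 0)
        nuclei = np.where(disk_mask(shape, (60, 180), 6), 2, nuclei).astype(np.int32)
        cells = separate_overlapping(
            [self._candidate(a, 1, (60, 60)), self._candidate(b, 2, (60, 180))],
            nuclei,
        )
        assert ((cells == 1) == a).all()
        assert ((cells == 2) == b).all()

    def test_symmetric_dumbbell_splits_evenly(self):
        shape = (160, 320)
        a = disk_mask(shape, (80, 120), 50)
        b = disk_mask(shape, (80, 200), 50)
        blob = a | b
        nuclei = np.where(disk_mask(shape, (80, 120), 8), 1, 0)
        nuclei = np.where(disk_mask(shape, (80, 200), 8), 2, nuclei).astype(np.int32)
        cands = [self._candidate(blob, 1, (80, 120)), self._candidate(blob, 2, (80, 200))]
        cells = separate_overlapping(cands, nuclei)
        area1, area2 = (cells == 1).sum(), (cells == 2).sum()
        assert abs(area1 - area2) / max(area1, area2) < 0.02
        assert (cells > 0).sum() == blob.sum()

    def test_pixel_conservation(self):
        shape = (160, 320)
        a = disk_mask(shape, (80, 110), 45)
        b = disk_mask(shape, (90, 190), 55)
        nuclei = np.where(disk_mask(shape, (80, 110), 7), 1, 0)
        nuclei = np.where(disk_mask(shape, (90, 190), 7), 2, nuclei).astype(np.int32)
        cands = [self._candidate(a, 1, (80, 110)), self._candidate(b, 2, (90, 190))]
        cells = separate_overlapping(cands, nuclei)
        assert (cells > 0).sum() == (a | b).sum()
        assert ((cells == 1) | (cells == 2)).sum() == (a | b).sum()

    def test_each_cell_keeps_its_nucleus_and_connectivity(self):
        from scipy import ndimage as ndi

        shape = (160, 320)
        a = disk_mask(shape, (80, 120), 50)
        b = disk_mask(shape, (80, 190), 50)
        blob = a | b
        nuclei = np.where(disk_mask(shape, (80, 120), 8), 1, 0)
        nuclei = np.where(disk_mask(shape, (80, 190), 8), 2, nuclei).astype(np.int32)
        cells = separate_overlapping(
            [self._candidate(blob, 1, (80, 120)), self._candidate(blob, 2, (80, 190))],
            nuclei,
        )
        for lbl in (1, 2):
            assert (cells[nuclei == lbl] == lbl).all()
            _, n = ndi.label(cells == lbl, structure=np.ones((3, 3), int))
            assert n == 1


class TestQCFilters:
    def _fixture(self):
        """10 constructed cells; three violate exactly one rule each."""
        px = 1.0  # 1 μm pixels keep the arithmetic transparent
        shape = (300, 300)
        region = RegionAnnotation("roi", box(0.0, 0.0, 299.0, 299.0))
        cells = np.zeros(shape, dtype=np.int32)
        nuclei = np.zeros(shape, dtype=np.int32)
        centers = [(40 + 55 * (k % 5), 60 + 110 * (k // 5)) for k in range(10)]
        for k, (c, r) in enumerate(centers, start=1):
            rr, cc = draw_disk((r, c), 5, shape=shape)  # ~78 μm² cell
            cells[rr, cc] = k
            rr, cc = draw_disk((r, c), 2, shape=shape)  # ~13 μm² nucleus
            nuclei[rr, cc] = k
        # violator 1: nucleus touching the region boundary
        cells[nuclei == 1] = 0
        nuclei[nuclei == 1] = 0
        rr, cc = draw_disk((1, 40), 3, shape=shape)
        nuclei[rr, cc] = 1
        rr, cc = draw_disk((3, 40), 6, shape=shape)
        cells[rr, cc] = 1
        # violator 2: nucleus area 4 px < 5 μm²
        nuclei[nuclei == 2] = 0
        r, c = 40, 115
        nuclei[r : r + 2, c : c + 2] = 2
        # violator 3: cell area 49 px < 50 μm²
        cells[cells == 3] = 0
        r, c = 40, 170
        cells[r - 3 : r + 4, c - 3 : c + 4] = 3  # 7x7 = 49 px
        rr, cc = draw_disk((r, c), 2, shape=shape)
        nuclei[rr, cc] = 3
        return cells, nuclei, region, px

    def test_exactly_the_violators_are_removed(self):
        cells, nuclei, region, px = self._fixture()
        params = SegmentationParams()
        out_cells, out_nuclei = apply_qc_filters(cells, nuclei, region, params, px)
        assert out_cells.max() == 7
        assert out_nuclei.max() == 7
        # labels match between cells and nuclei after relabeling
        for lbl in range(1, 8):
            assert (out_cells[out_nuclei == lbl] == lbl).all()

    def test_boundary_values_kept(self):
        """Nucleus exactly 5 μm² and cell exactly 50 μm² survive (strict <)."""
        px = 1.0
        shape = (100, 100)
        region = RegionAnnotation("roi", box(0.0, 0.0, 99.0, 99.0))
        cells = np.zeros(shape, dtype=np.int32)
        nuclei = np.zeros(shape, dtype=np.int32)
        cells[40:50, 40:45] = 1  # 50 px = 50 μm²
        nuclei[42:47, 41:42] = 1  # 5 px = 5 μm²
        out_cells, out_nuclei = apply_qc_filters(
            cells, nuclei, region, SegmentationParams(), px
        )
        assert out_cells.max() == 1 and out_nuclei.max() == 1

    def test_idempotent(self):
        cells, nuclei, region, px = self._fixture()
        params = SegmentationParams()
        once = apply_qc_filters(cells, nuclei, region, params, px)
        twice = apply_qc_filters(once[0], once[1], region, params, px)
        np.testing.assert_array_equal(once[0], twice[0])
        np.testing.assert_array_equal(once[1], twice[1])


class TestEndToEndSegmentation:
    def test_all_truth_cells_recovered_bijectively(self, e2e_scene, e2e_segmentation, e2e_matched):
        cells, nuclei = e2e_segmentation
        assert int(cells.max()) == len(e2e_scene.truth_cells)
        labels = [lbl for _tc, lbl in e2e_matched]
        assert 0 not in labels
        assert len(set(labels)) == len(labels)

    def test_every_cell_contains_its_nucleus(self, e2e_segmentation):
        cells, nuclei = e2e_segmentation
        for lbl in range(1, int(cells.max()) + 1):
            sel = nuclei == lbl
            assert sel.any()
            assert (cells[sel] == lbl).all()

    def test_ramified_jaccard_at_least_080(self, e2e_scene, e2e_segmentation, e2e_matched):
        cells, _ = e2e_segmentation
        for tc, lbl in e2e_matched:
            if tc.phenotype != "ramified":
                continue
            truth = tc.cell_mask.to_full(cells.shape)
            seg = cells == lbl
            jacc = (truth & seg).sum() / (truth | seg).sum()
            assert jacc >= 0.8
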