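"""Spot detection, segmentation, free-spot classification, colocalization
and density: shape-descriptor hand values, generator round trips, and
matching invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitopits.detection import (DetectionParams, ENDOCYTOSIS_PRESET,
                                SegmentationMask, SegmentationParams,
                                SpotRecord, circularity, classify_free_spots,
                                colocalize, detect_spots, measure_components,
                                segment_mitochondria, spot_density)
from mitopits.synthetic import (ImagingModel, SpotTruth, render_scene)

from conftest import make_tube_graph


def _make_spot(x, y, area_um2=0.05):
    return SpotRecord(centroid_px=(x, y), centroid_nm=(x * 45, y * 45),
                      area_um2=area_um2, circularity=1.0, mean_intensity=1.0)


def _separated_spots(n, field_nm, spacing_nm=2000.0, margin_nm=1500.0):
    """n free-class spots on a grid, pairwise separation >= spacing."""
    per_row = int((field_nm[0] - 2 * margin_nm) // spacing_nm) + 1
    spots = []
    for i in range(n):
        x = margin_nm + (i % per_row) * spacing_nm
        y = margin_nm + (i // per_row) * spacing_nm
        spots.append(SpotTruth(position_nm=np.array([x, y]),
                               true_class="free"))
    return spots


class TestShapeDescriptors:
    def test_disc_circularity_near_one(self):
        yy, xx = np.mgrid[:80, :80]
        disc = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 30**2)
        rec = measure_components(
            disc, disc.astype(float),
            DetectionParams(max_area_um2=50.0, min_circularity=0.0),
            pixel_size_nm=45.0)
        assert len(rec) == 1
        assert rec[0].circularity == pytest.approx(1.0, abs=0.05)

    def test_square_circularity_is_pi_over_four(self):
        # hand formula: 4*pi*a^2 / (4a)^2 = pi/4 = 0.785
        img = np.zeros((70, 70), dtype=bool)
        img[10:60, 10:60] = True
        rec = measure_components(
            img, img.astype(float),
            DetectionParams(max_area_um2=50.0, min_circularity=0.0,
                            max_circularity=1.0),
            pixel_size_nm=45.0)
        assert len(rec) == 1
        assert rec[0].circularity == pytest.approx(np.pi / 4.0, abs=0.05)

    def test_single_pixel_counts_as_disc(self):
        assert circularity(1.0, 0.0) == 1.0


class TestDetectSpots:
    def test_planted_spots_recovered_exactly(self, noiseless_imaging):
        g = make_tube_graph(3000.0, field_nm=(46080.0, 46080.0))
        spots = _separated_spots(20, (46080.0, 46080.0))
        scene = render_scene(g, spots, noiseless_imaging, seed=0)
        det = detect_spots(scene.channels["hook"])
        assert len(det) == 20
        truth = np.array([s.position_nm for s in spots]) / 45.0
        for rec in det:
            d = np.min(np.linalg.norm(truth - np.array(rec.centroid_px),
                                      axis=1))
            assert d < 1.0

    def test_filter_monotonicity(self, noiseless_imaging):
        g = make_tube_graph(3000.0, field_nm=(46080.0, 46080.0))
        spots = _separated_spots(15, (46080.0, 46080.0))
        scene = render_scene(g, spots, noiseless_imaging, seed=0)
        base = DetectionParams()
        n_base = len(detect_spots(scene.channels["hook"], base))
        for update in ({"min_area_um2": 0.08}, {"max_area_um2": 0.09},
                       {"min_circularity": 0.95}):
            tight = base.model_copy(update=update)
            assert len(detect_spots(scene.channels["hook"], tight)) <= n_base

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((32, 32))
        img[5, 5] = np.nan
        with pytest.raises(ValueError):
            detect_spots(img)

    def test_blank_image_yields_empty_result(self):
        with pytest.warns(UserWarning):
            assert detect_spots(np.zeros((64, 64))) == []

    def test_endocytosis_preset_bounds(self):
        assert ENDOCYTOSIS_PRESET.min_area_um2 == 0.0
        assert ENDOCYTOSIS_PRESET.max_area_um2 == 1.0
        assert ENDOCYTOSIS_PRESET.min_circularity == 0.3


class TestSegmentation:
    def test_noiseless_tube_mask_overlaps_truth(self, noiseless_imaging):
        g = make_tube_graph(5000.0, field_nm=(23040.0, 23040.0))
        scene = render_scene(g, [], noiseless_imaging, seed=0)
        mask = segment_mitochondria(scene.channels["anchor"])
        # ground-truth footprint: within one radius of the axis
        yy, xx = np.mgrid[:mask.mask.shape[0], :mask.mask.shape[1]]
        pts = g.edges[0].polyline_nm / 45.0
        d2 = np.full(mask.mask.shape, np.inf)
        for x, y in pts:
            d2 = np.minimum(d2, (xx - x) ** 2 + (yy - y) ** 2)
        truth = d2 <= (250.0 / 45.0) ** 2
        iou = (mask.mask & truth).sum() / (mask.mask | truth).sum()
        assert iou >= 0.9

    def test_manual_threshold_above_uniform_empty(self):
        mask = segment_mitochondria(np.full((32, 32), 5.0),
                                    SegmentationParams(threshold=10.0))
        assert not mask.mask.any()

    def test_constant_image_automatic_threshold_warns_empty(self):
        with pytest.warns(UserWarning):
            mask = segment_mitochondria(np.zeros((32, 32)))
        assert not mask.mask.any()


class TestClassifyFreeSpots:
    def test_all_inside_mask(self):
        mask = SegmentationMask(np.ones((50, 50), dtype=bool), 45.0)
        spots = [_make_spot(10, 10), _make_spot(30, 40)]
        labelled, pct = classify_free_spots(spots, mask)
        assert pct == 0.0
        assert all(s.is_free is False for s in labelled)

    def test_empty_mask_all_free(self):
        mask = SegmentationMask(np.zeros((50, 50), dtype=bool), 45.0)
        _, pct = classify_free_spots([_make_spot(10, 10)], mask)
        assert pct == 100.0

    def test_no_spots_undefined(self):
        mask = SegmentationMask(np.ones((10, 10), dtype=bool), 45.0)
        labelled, pct = classify_free_spots([], mask)
        assert labelled == [] and pct is None

    def test_order_invariance(self):
        mask = SegmentationMask(np.zeros((50, 50), dtype=bool), 45.0)
        mask.mask[:25] = True
        spots = [_make_spot(5, 5), _make_spot(40, 45), _make_spot(20, 10)]
        _, pct1 = classify_free_spots(spots, mask)
        _, pct2 = classify_free_spots(spots[::-1], mask)
        assert pct1 == pct2


class TestColocalize:
    def test_identical_lists_full_overlap(self):
        spots = [_make_spot(i * 10, i * 10) for i in range(5)]
        res = colocalize(spots, spots)
        assert res.pct_A_with_B == res.pct_B_with_A == 100.0

    def test_disjoint_lists_zero(self):
        a = [_make_spot(0, 0)]
        b = [_make_spot(30, 30)]
        res = colocalize(a, b)
        assert res.pct_A_with_B == res.pct_B_with_A == 0.0
        assert res.n_matched == 0

    def test_partial_overlap_matches_brute_force(self):
        # A = 10 spots; B = A's first 6 plus 4 distant -> 60% both ways
        a = [_make_spot(10 * i, 0) for i in range(10)]
        b = a[:6] + [_make_spot(10 * i, 500) for i in range(4)]
        res = colocalize(a, b)
        assert res.n_matched == 6
        assert res.pct_A_with_B == pytest.approx(60.0)
        assert res.pct_B_with_A == pytest.approx(60.0)

    @given(st.integers(0, 2**31 - 1))
    def test_match_count_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = [_make_spot(x, y) for x, y in rng.uniform(0, 30, (8, 2))]
        b = [_make_spot(x, y) for x, y in rng.uniform(0, 30, (11, 2))]
        assert colocalize(a, b).n_matched == colocalize(b, a).n_matched


class TestSpotDensity:
    def test_hand_arithmetic(self):
        # 50 spots on 500 um^2 -> 10 per 100 um^2
        n_px = int(500.0 / (0.045**2))
        side = int(np.ceil(np.sqrt(n_px)))
        mask = np.zeros((side, side + 10), dtype=bool)
        mask.flat[:n_px] = True
        sm = SegmentationMask(mask, 45.0)
        spots = [_make_spot(1, 1)] * 50
        assert spot_density(spots, sm) == pytest.approx(10.0, rel=1e-4)

    def test_zero_spots(self):
        sm = SegmentationMask(np.ones((100, 100), dtype=bool), 45.0)
        assert spot_density([], sm) == 0.0

    def test_empty_mask_raises(self):
        sm = SegmentationMask(np.zeros((10, 10), dtype=bool), 45.0)
        with pytest.raises(ValueError):
            spot_density([_make_spot(1, 1)], sm)
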