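"""Dish detection, cropping, binarization and segment-map contracts."""

import numpy as np
import pytest
from skimage import measure

import platepick as pp
from conftest import SCALE, SIZE, make_params, run_detection


class TestDetectDish:
    def test_centered_dish_zero_offset(self, std_plate):
        image, gt = std_plate
        geom = pp.detect_dish(image, gt.dish.center_px, SCALE)
        off = geom.offset_to_labware_px
        assert abs(off[0]) < 1.5 and abs(off[1]) < 1.5

    def test_shifted_dish_offset_by_construction(self):
        params = make_params(dish_center_px=(270.0, 230.0), n_colonies=10,
                             seed=21)
        image, _ = pp.generate_plate(params)
        geom = pp.detect_dish(image, (250.0, 250.0), SCALE)
        assert geom.offset_to_labware_px[0] == pytest.approx(20.0, abs=1.5)
        assert geom.offset_to_labware_px[1] == pytest.approx(-20.0, abs=1.5)

    def test_radius_within_2px_on_benchmark_plates(self):
        b = pp.benchmark_v1()
        plates = pp.generate_benchmark(
            pp.BenchmarkParams(n_plates=3, master_seed=b.master_seed))
        for image, gt in plates:
            geom = pp.detect_dish(image, (500.0, 500.0),
                                  gt.params.scale_mm_per_px)
            assert abs(geom.radius_px - gt.dish.outer_radius_px) < 2.0

    def test_no_dish_raises(self):
        rng = np.random.default_rng(0)
        noise = rng.integers(0, 40, size=(SIZE, SIZE, 3), dtype=np.uint8)
        with pytest.raises(pp.DishNotFoundError):
            pp.detect_dish(pp.PlateImage(noise), (250.0, 250.0), SCALE)


class TestCropDish:
    def test_full_image_bbox_is_identity(self, std_plate):
        image, _ = std_plate
        geom = pp.DishGeometry((250.0, 250.0), 220.0, (0, 0, SIZE, SIZE),
                               (0.0, 0.0))
        crop = pp.crop_dish(image, geom)
        assert np.array_equal(crop.rgb, image.rgb)

    def test_known_bbox_shape(self, std_plate):
        image, _ = std_plate
        geom = pp.DishGeometry((250.0, 250.0), 200.0, (50, 50, 450, 450),
                               (0.0, 0.0))
        crop = pp.crop_dish(image, geom)
        assert crop.shape == (400, 400)
        assert crop.origin == (50, 50)

    def test_local_center_arithmetic(self, std_detection):
        det, _ = std_detection
        geom, crop = det["geom"], det["crop"]
        assert crop.dish_center_local[0] == pytest.approx(
            geom.center_px[0] - geom.bbox[0])
        assert crop.dish_center_local[1] == pytest.approx(
            geom.center_px[1] - geom.bbox[1])

    def test_degenerate_bbox_rejected(self, std_plate):
        image, _ = std_plate
        geom = pp.DishGeometry((10.0, 10.0), 5.0, (100, 100, 100, 300),
                               (0.0, 0.0))
        with pytest.raises(ValueError):
            pp.crop_dish(image, geom)


class TestSegmentInner:
    def test_blank_agar_empty_mask(self):
        image, gt = pp.generate_plate(make_params(n_colonies=0,
                                                  artifact_count=0, seed=1))
        det = run_detection(image, gt)
        assert det["inner"].sum() == 0

    def test_components_equal_their_convex_hulls(self, std_detection):
        det, _ = std_detection
        labels = measure.label(det["inner"], connectivity=2)
        for region in measure.regionprops(labels):
            assert region.image.sum() == region.image_convex.sum()

    def test_clean_plate_count_matches_ground_truth(self, clean_plate):
        image, gt = clean_plate
        det = run_detection(image, gt)
        n = measure.label(det["inner"], connectivity=2).max()
        assert n == gt.n_colonies


class TestSegmentBorder:
    def test_wall_only_annulus_is_empty(self):
        image, gt = pp.generate_plate(make_params(n_colonies=0,
                                                  artifact_count=0, seed=1))
        det = run_detection(image, gt)
        assert det["border"].sum() == 0

    def test_straddling_colony_yields_blob(self):
        # place one colony with its centre right at the unpickable margin
        # so its disc straddles the inner-disc boundary of the border stage
        params = make_params(n_colonies=1, border_fraction=1.0,
                             group_fraction=0.0, artifact_count=0,
                             illumination_gradient=0.0, noise_sigma=0.0,
                             colony_radius_range_mm=(1.8, 1.9),
                             color_phenotypes=(((235, 231, 222), 1.0),),
                             seed=17)
        image, gt = pp.generate_plate(params)
        geom = pp.detect_dish(image, (250.0, 250.0), SCALE)
        crop = pp.crop_dish(image, geom)
        border = pp.segment_border(crop, geom,
                                   pp.BorderParams(scale_mm_per_px=SCALE))
        assert border.sum() > 0

    def test_output_confined_to_annulus(self, std_detection):
        det, _ = std_detection
        geom, crop, border = det["geom"], det["crop"], det["border"]
        p = pp.BorderParams(scale_mm_per_px=SCALE)
        yy, xx = np.mgrid[0:border.shape[0], 0:border.shape[1]]
        d = np.hypot(xx - crop.dish_center_local[0],
                     yy - crop.dish_center_local[1])
        annulus = d >= geom.inner_radius_px - p.overlap_mm / SCALE
        assert not (border & ~annulus).any()


class TestBuildSegmentMap:
    def test_empty_masks_two_background_segments(self, std_detection):
        det, _ = std_detection
        shape = det["crop"].shape
        empty = np.zeros(shape, dtype=bool)
        segmap = pp.build_segment_map(empty, empty, det["geom"],
                                      det["crop"].dish_center_local)
        assert len(segmap.records) == 2
        assert segmap.is_partition()

    def test_five_components_seven_segments(self, std_detection):
        det, _ = std_detection
        shape = det["crop"].shape
        inner = np.zeros(shape, dtype=bool)
        cx, cy = det["crop"].dish_center_local
        for k in range(5):
            x = int(cx) - 100 + 50 * k
            inner[int(cy) - 3:int(cy) + 3, x - 3:x + 3] = True
        empty = np.zeros(shape, dtype=bool)
        segmap = pp.build_segment_map(inner, empty, det["geom"],
                                      det["crop"].dish_center_local)
        assert len(segmap.records) == 7
        assert len(segmap.colony_ids()) == 5

    def test_segment_map_is_partition(self, std_detection):
        det, _ = std_detection
        assert det["segmap"].is_partition()


def test_rotation_equivariant_counting(clean_plate):
    """Segmenting the 90-degree rotated plate finds the same colonies."""
    image, gt = clean_plate
    det = run_detection(image, gt)
    rot = pp.PlateImage(np.ascontiguousarray(np.rot90(image.rgb)),
                        scale_mm_per_px=SCALE)
    # dish centre moves under rotation; ground truth only supplies n
    geom = pp.detect_dish(rot, (SIZE / 2, SIZE / 2), SCALE)
    crop = pp.crop_dish(rot, geom)
    inner = pp.segment_inner(crop, geom, pp.InnerParams(scale_mm_per_px=SCALE))
    border = pp.segment_border(crop, geom,
                               pp.BorderParams(scale_mm_per_px=SCALE))
    segmap = pp.build_segment_map(inner, border, geom, crop.dish_center_local)
    fps_rot = pp.split_groups(segmap, crop.rgb,
                              pp.SplitParams(scale_mm_per_px=SCALE))
    assert len(fps_rot) == len(det["footprints"])
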