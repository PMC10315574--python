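"""Group splitting, footprint measurement and pickability flags."""

import math

import numpy as np
import pytest

import platepick as pp
from conftest import SCALE, make_params, run_detection


def _footprint_from_disc(shape, cx, cy, r, fid=0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return pp.ColonyFootprint(
        id=fid, bbox=(x0, y0, x1, y1), mask=mask[y0:y1, x0:x1],
        centroid=(xs.mean(), ys.mean()), area_px=int(mask.sum()))


def _merged_pair_fixture(centers=((40.0, 50.0), (62.0, 50.0)), r=12.0,
                         amp=120.0, shape=(100, 100)):
    """A single segment covering two overlapping Gaussian domes."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    gray = np.full(shape, 95.0)
    mask = np.zeros(shape, dtype=bool)
    for cx, cy in centers:
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        dome = amp * np.exp(-d2 / (2 * (r / 2) ** 2))
        dome[d2 > r * r] = 0.0
        gray = np.maximum(gray, 95.0 + dome)
        mask |= d2 <= r * r
    labels = np.full(shape, 2, dtype=np.int32)
    labels[mask] = 3
    records = {2: pp.SegmentRecord(2, "background", "0 colonies"),
               3: pp.SegmentRecord(3, "colonies", "1 colony", 1)}
    return gray, pp.SegmentMap(labels, records)


class TestSplitGroups:
    def test_single_dome_single_footprint(self, clean_plate):
        image, gt = clean_plate
        det = run_detection(image, gt)
        assert all(fp.n_colonies_in_parent_segment == 1
                   for fp in det["footprints"])
        assert len(det["footprints"]) == gt.n_colonies

    def test_merged_pair_split_near_true_centers(self):
        centers = ((40.0, 50.0), (62.0, 50.0))
        gray, segmap = _merged_pair_fixture(centers)
        fps = pp.split_groups(segmap, gray,
                              pp.SplitParams(scale_mm_per_px=SCALE))
        assert len(fps) == 2
        got = sorted(fp.centroid for fp in fps)
        for (gx, gy), (tx, ty) in zip(got, sorted(centers)):
            # within 0.5 mm = 2.5 px at this scale
            assert math.hypot(gx - tx, gy - ty) < 0.5 / SCALE

    def test_children_partition_parent(self):
        gray, segmap = _merged_pair_fixture()
        fps = pp.split_groups(segmap, gray,
                              pp.SplitParams(scale_mm_per_px=SCALE))
        parent = segmap.labels == 3
        union = np.zeros_like(parent)
        overlap = 0
        for fp in fps:
            full = np.zeros_like(parent)
            x0, y0, x1, y1 = fp.bbox
            full[y0:y1, x0:x1] = fp.mask
            overlap += int((union & full).sum())
            union |= full
        assert overlap == 0
        assert np.array_equal(union, parent)

    def test_sublabel_updated_for_groups(self):
        gray, segmap = _merged_pair_fixture()
        fps = pp.split_groups(segmap, gray,
                              pp.SplitParams(scale_mm_per_px=SCALE))
        assert segmap.records[3].sublabel == "2 colonies"
        assert all(fp.n_colonies_in_parent_segment == 2 for fp in fps)

    def test_generator_pair_resolved_into_two_footprints(self, pair_plate):
        image, gt = pair_plate
        det = run_detection(image, gt)
        fps = det["footprints"]
        assert len(fps) == 2
        cx, cy = det["crop"].dish_center_local
        det_mm = np.array([[(fp.centroid[0] - cx) * SCALE,
                            (fp.centroid[1] - cy) * SCALE] for fp in fps])
        tru = gt.colonies[["x_mm", "y_mm"]].to_numpy()
        d = np.hypot(*(det_mm[:, None, :] - tru[None, :, :]).transpose(2, 0, 1))
        assert d.min(axis=0).max() < 0.5


class TestMeasureFootprints:
    def test_pure_blue_hue_240(self):
        rgb = np.zeros((40, 40, 3), dtype=np.uint8)
        rgb[..., 2] = 255
        fp = _footprint_from_disc((40, 40), 20, 20, 10)
        pp.measure_footprints([fp], rgb, None, 0.1)
        assert fp.mean_hsv[0] == pytest.approx(240.0, abs=1e-6)
        assert fp.mean_hsv[1] == pytest.approx(1.0)
        assert fp.mean_hsv[2] == pytest.approx(1.0)

    def test_area_scaling_arithmetic(self):
        rgb = np.full((30, 30, 3), 128, dtype=np.uint8)
        fp = _footprint_from_disc((30, 30), 15, 15, 8)
        fp.area_px = 100           # fix the count for exact arithmetic
        mask = np.ones((10, 10), dtype=bool)
        fp.mask = mask
        fp.bbox = (5, 5, 15, 15)
        pp.measure_footprints([fp], rgb, None, 0.1)
        assert fp.area_mm2 == pytest.approx(1.0)
        assert fp.equivalent_diameter_mm == pytest.approx(
            2 * math.sqrt(1.0 / math.pi))

    def test_scale_covariance(self):
        rgb = np.full((30, 30, 3), 128, dtype=np.uint8)
        fp1 = _footprint_from_disc((30, 30), 15, 15, 8)
        fp2 = _footprint_from_disc((30, 30), 15, 15, 8)
        pp.measure_footprints([fp1], rgb, None, 0.1)
        pp.measure_footprints([fp2], rgb, None, 0.2)
        assert fp2.area_mm2 == pytest.approx(4 * fp1.area_mm2)
        assert fp2.equivalent_diameter_mm == pytest.approx(
            2 * fp1.equivalent_diameter_mm)

    def test_fluorescence_mean_matches_generator_level(self):
        params = make_params(n_colonies=12, group_fraction=0.0,
                             border_fraction=0.0, artifact_count=0,
                             illumination_gradient=0.0, noise_sigma=2.0,
                             seed=23)
        image, gt = pp.generate_plate(params)
        shape = image.rgb.shape[:2]
        for _, row in gt.colonies.iterrows():
            r_px = row.radius_mm / SCALE
            fp = _footprint_from_disc(shape, row.x_px, row.y_px, r_px - 1)
            pp.measure_footprints([fp], image.rgb, image.fluorescence, SCALE)
            assert fp.mean_fluorescence == pytest.approx(
                row.fluorescence, abs=params.noise_sigma)

    def test_empty_mask_rejected(self):
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        fp = pp.ColonyFootprint(id=0, bbox=(0, 0, 2, 2),
                                mask=np.zeros((2, 2), dtype=bool),
                                centroid=(1.0, 1.0), area_px=0)
        with pytest.raises(ValueError):
            pp.measure_footprints([fp], rgb, None, 0.1)


class TestFlagPickable:
    def _geom(self):
        return pp.DishGeometry((250.0, 250.0), 220.0, (30, 30, 470, 470),
                               (0.0, 0.0), wall_px=10.0)

    def test_center_colony_pickable(self):
        geom = self._geom()
        fp = _footprint_from_disc((440, 440), 220, 220, 8)
        pp.measure_footprints([fp], np.full((440, 440, 3), 128, np.uint8),
                              None, SCALE)
        pp.flag_pickable([fp], geom, 2.0, SCALE, 1.0, (220.0, 220.0))
        assert fp.pickable is True

    def test_wall_colony_not_pickable(self):
        geom = self._geom()
        fp = _footprint_from_disc((440, 440), 428, 220, 8)
        pp.measure_footprints([fp], np.full((440, 440, 3), 128, np.uint8),
                              None, SCALE)
        pp.flag_pickable([fp], geom, 2.0, SCALE, 1.0, (220.0, 220.0))
        assert fp.pickable is False

    def test_tiny_colony_below_min_diameter_not_pickable(self):
        geom = self._geom()
        fp = _footprint_from_disc((440, 440), 220, 220, 2)   # ~0.8 mm diam
        pp.measure_footprints([fp], np.full((440, 440, 3), 128, np.uint8),
                              None, SCALE)
        pp.flag_pickable([fp], geom, 2.0, SCALE, min_diameter_mm=1.0,
                         dish_center_local=(220.0, 220.0))
        assert fp.pickable is False


def test_fluorescence_ranking_monotone(std_detection):
    """Footprint fluorescence ordering reproduces the generator's levels."""
    det, gt = std_detection
    fps = [fp for fp in det["footprints"]
           if fp.n_colonies_in_parent_segment == 1]
    tru = gt.colonies[["x_mm", "y_mm"]].to_numpy()
    levels = gt.colonies["fluorescence"].to_numpy()
    cx, cy = det["crop"].dish_center_local
    bright, dim = [], []
    for fp in fps:
        dmm = ((fp.centroid[0] - cx) * SCALE, (fp.centroid[1] - cy) * SCALE)
        d = np.hypot(tru[:, 0] - dmm[0], tru[:, 1] - dmm[1])
        if d.min() > 0.5:
            continue
        (bright if levels[d.argmin()] == 200 else dim).append(
            fp.mean_fluorescence)
    assert bright and dim
    assert min(bright) > max(dim)
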