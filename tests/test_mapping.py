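"""Pixel-to-robot coordinate mapping and picklist I/O."""

import math

import numpy as np
import pytest

import platepick as pp


FRAME = pp.CameraFrame((480.0, 505.0), 0.1)


class TestColonyOffsetPixels:
    def test_colony_at_dish_at_labware_center(self):
        assert pp.colony_offset_pixels((100.0, 100.0), (100.0, 100.0),
                                       (0.0, 0.0)) == (0.0, 0.0)

    def test_vector_sum(self):
        off = pp.colony_offset_pixels((110.0, 100.0), (100.0, 100.0),
                                      (5.0, 5.0))
        assert off == (15.0, 5.0)

    def test_equals_global_offset_bypassing_crop(self):
        """Brute-force oracle: the two-step sum equals c_i_global - O_lab."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            o_lab = rng.uniform(0, 1000, 2)
            o_pet = rng.uniform(0, 1000, 2)
            origin = rng.integers(0, 200, 2).astype(float)
            c_global = rng.uniform(0, 1000, 2)
            c_local = c_global - origin
            o_pet_prime = o_pet - origin
            dish_offset = o_pet - o_lab
            got = pp.colony_offset_pixels(tuple(c_local), tuple(o_pet_prime),
                                          tuple(dish_offset))
            want = c_global - o_lab
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)


class TestPixelToRobot:
    def test_zero_maps_to_zero(self):
        assert pp.pixel_to_robot((0.0, 0.0), FRAME) == (0.0, 0.0)

    def test_norm_preserved_up_to_scale(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.uniform(-500, 500, 2)
            out = pp.pixel_to_robot(tuple(v), FRAME)
            assert math.hypot(*out) == pytest.approx(
                FRAME.scale_mm_per_px * math.hypot(*v))

    def test_rotation_four_times_is_identity(self):
        def rot90_ccw(u, v):
            return (-v, u)
        vec = (3.7, -2.1)
        out = vec
        for _ in range(4):
            out = rot90_ccw(*out)
        assert out == pytest.approx(vec)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(2)
        for flags in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
            frame = pp.CameraFrame((500.0, 500.0), 0.1, flags)
            for _ in range(10):
                v = tuple(rng.uniform(-400, 400, 2))
                back = pp.robot_to_pixel(pp.pixel_to_robot(v, frame), frame)
                assert back[0] == pytest.approx(v[0], abs=1e-6)
                assert back[1] == pytest.approx(v[1], abs=1e-6)

    def test_invalid_frame_rejected(self):
        with pytest.raises(ValueError):
            pp.CameraFrame((0.0, 0.0), -0.1)
        with pytest.raises(ValueError):
            pp.CameraFrame((0.0, 0.0), 0.1, (2, 1))


def _fp(fid, centroid, pickable=True):
    fp = pp.ColonyFootprint(id=fid, bbox=(0, 0, 1, 1),
                            mask=np.ones((1, 1), dtype=bool),
                            centroid=centroid, area_px=1)
    fp.pickable = pickable
    return fp


GEOM = pp.DishGeometry((520.0, 480.0), 435.0, (85, 45, 956, 916),
                       (20.0, -20.0), wall_px=20.0)


class TestBuildPicklist:
    def test_empty_selection_empty_picklist(self):
        frame = pp.CameraFrame((500.0, 500.0), 0.1)
        assert pp.build_picklist([], [], GEOM, frame) == []

    def test_length_and_order(self):
        frame = pp.CameraFrame((500.0, 500.0), 0.1)
        fps = [_fp(i, (400.0 + i, 400.0)) for i in range(30)]
        sel = [(i, f"A{i + 1}") for i in range(30)]
        targets = pp.build_picklist(sel, fps, GEOM, frame)
        assert len(targets) == 30
        assert [t.pick_order for t in targets] == list(range(1, 31))
        assert targets[0].dest_well == "A1"

    def test_unpickable_colony_rejected(self):
        frame = pp.CameraFrame((500.0, 500.0), 0.1)
        fps = [_fp(0, (400.0, 400.0), pickable=False)]
        with pytest.raises(ValueError):
            pp.build_picklist([0], fps, GEOM, frame)

    def test_unknown_id_rejected(self):
        frame = pp.CameraFrame((500.0, 500.0), 0.1)
        with pytest.raises(KeyError):
            pp.build_picklist([7], [], GEOM, frame)

    def test_round_trip_recovers_centroid(self):
        """Inverse-mapping a PickTarget recovers c_i within 1e-6 px."""
        frame = pp.CameraFrame((500.0, 500.0), 0.1, (1, -1))
        rng = np.random.default_rng(9)
        fps = [_fp(i, tuple(rng.uniform(200, 800, 2))) for i in range(20)]
        targets = pp.build_picklist(list(range(20)), fps, GEOM, frame)
        o_pet_prime = GEOM.center_local
        for fp, t in zip(fps, targets):
            off_px = pp.robot_to_pixel(t.robot_offset_mm, frame)
            ci = (off_px[0] - GEOM.offset_to_labware_px[0] + o_pet_prime[0],
                  off_px[1] - GEOM.offset_to_labware_px[1] + o_pet_prime[1])
            assert ci[0] == pytest.approx(fp.centroid[0], abs=1e-6)
            assert ci[1] == pytest.approx(fp.centroid[1], abs=1e-6)


def test_translation_equivariance():
    """Shifting the dish shifts every robot offset by one rotated vector."""
    frame = pp.CameraFrame((500.0, 500.0), 0.1)
    shift = (30.0, -12.0)
    geom_a = GEOM
    geom_b = pp.DishGeometry(
        (GEOM.center_px[0] + shift[0], GEOM.center_px[1] + shift[1]),
        GEOM.radius_px,
        (GEOM.bbox[0] + int(shift[0]), GEOM.bbox[1] + int(shift[1]),
         GEOM.bbox[2] + int(shift[0]), GEOM.bbox[3] + int(shift[1])),
        (GEOM.offset_to_labware_px[0] + shift[0],
         GEOM.offset_to_labware_px[1] + shift[1]),
        wall_px=GEOM.wall_px)
    fps = [_fp(i, (300.0 + 17 * i, 350.0 + 11 * i)) for i in range(5)]
    # same crop-local centroids on both plates; only the dish moved
    t_a = pp.build_picklist(list(range(5)), fps, geom_a, frame)
    t_b = pp.build_picklist(list(range(5)), fps, geom_b, frame)
    # the crop origin moved by int(shift), the centre by shift
    frac = (shift[0] - int(shift[0]), shift[1] - int(shift[1]))
    expected = pp.pixel_to_robot((shift[0] - frac[0], shift[1] - frac[1]),
                                 frame)
    for a, b in zip(t_a, t_b):
        got = (b.robot_offset_mm[0] - a.robot_offset_mm[0],
               b.robot_offset_mm[1] - a.robot_offset_mm[1])
        assert got[0] == pytest.approx(expected[0], abs=1e-9)
        assert got[1] == pytest.approx(expected[1], abs=1e-9)


class TestPicklistCsv:
    def test_empty_picklist_header_only(self, tmp_path):
        path = tmp_path / "p.csv"
        pp.write_picklist_csv([], path)
        lines = path.read_text().strip().splitlines()
        assert lines == [",".join(pp.mapping.PICKLIST_HEADER)]

    def test_round_trip(self, tmp_path):
        targets = [pp.PickTarget(3, (1.25, -7.5), 0.875, 1, "A1"),
                   pp.PickTarget(9, (-0.333333, 2.0), 0.5, 2, "B1")]
        path = tmp_path / "p.csv"
        pp.write_picklist_csv(targets, path)
        back = pp.read_picklist_csv(path)
        for a, b in zip(targets, back):
            assert a.colony_id == b.colony_id
            assert a.robot_offset_mm[0] == pytest.approx(
                b.robot_offset_mm[0], abs=1e-6)
            assert a.dest_well == b.dest_well
            assert a.pick_order == b.pick_order

    def test_n_targets_n_plus_one_lines(self, tmp_path):
        targets = [pp.PickTarget(i, (0.0, 0.0), 0.1, i + 1, "A1")
                   for i in range(7)]
        path = tmp_path / "p.csv"
        pp.write_picklist_csv(targets, path)
        assert len(path.read_text().strip().splitlines()) == 8
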