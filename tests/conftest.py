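"""Shared fixtures: small synthetic plates and a detection-chain helper."""

import numpy as np
import pytest

import platepick as pp

# Unit-test plates use a coarser camera scale (0.2 mm/px, 500 px frame)
# than the canonical benchmark so each one renders in ~0.2 s; every
# length parameter in the pipeline is specified in mm, so the defaults
# carry over unchanged.
SCALE = 0.2
SIZE = 500


def make_params(**kw):
    defaults = dict(image_size_px=SIZE, scale_mm_per_px=SCALE,
                    n_colonies=40, group_fraction=0.1, border_fraction=0.05,
                    artifact_count=2, illumination_gradient=0.05,
                    noise_sigma=2.0, seed=11)
    defaults.update(kw)
    return pp.PlateParams(**defaults)


def run_detection(image, gt, labware_center=None):
    """Run dish detection through group splitting; returns a dict of
    intermediates."""
    scale = gt.params.scale_mm_per_px
    if labware_center is None:
        c = gt.params.image_size_px / 2.0
        labware_center = (c, c)
    geom = pp.detect_dish(image, labware_center, scale)
    crop = pp.crop_dish(image, geom)
    inner = pp.segment_inner(crop, geom, pp.InnerParams(scale_mm_per_px=scale))
    border = pp.segment_border(crop, geom,
                               pp.BorderParams(scale_mm_per_px=scale))
    segmap = pp.build_segment_map(inner, border, geom, crop.dish_center_local)
    fps = pp.split_groups(segmap, crop.rgb,
                          pp.SplitParams(scale_mm_per_px=scale))
    pp.measure_footprints(fps, crop.rgb, crop.fluorescence, scale)
    pp.flag_pickable(fps, geom, gt.params.margin_mm, scale,
                     gt.params.min_pick_diameter_mm, crop.dish_center_local)
    return {"geom": geom, "crop": crop, "inner": inner, "border": border,
            "segmap": segmap, "footprints": fps, "scale": scale}


@pytest.fixture(scope="session")
def std_plate():
    """A realistic mid-density plate with groups, border colonies, specks."""
    return pp.generate_plate(make_params())


@pytest.fixture(scope="session")
def std_detection(std_plate):
    image, gt = std_plate
    return run_detection(image, gt), gt


@pytest.fixture(scope="session")
def clean_plate():
    """Noiseless, well-separated colonies: segmentation oracle conditions."""
    params = make_params(n_colonies=25, group_fraction=0.0,
                         border_fraction=0.0, artifact_count=0,
                         illumination_gradient=0.0, noise_sigma=0.0, seed=3)
    return pp.generate_plate(params)


@pytest.fixture(scope="session")
def pair_plate():
    """Exactly one touching pair on an otherwise clean plate."""
    params = make_params(n_colonies=2, group_fraction=1.0,
                         border_fraction=0.0, artifact_count=0,
                         illumination_gradient=0.0, noise_sigma=0.0,
                         colony_radius_range_mm=(1.5, 2.0), seed=5)
    return pp.generate_plate(params)
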