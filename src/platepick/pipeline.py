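"""End-to-end pipeline: image -> detection -> screening -> picklist.

The software half of the colony-picking workflow: detect the dish, crop,
segment inner disc and wall annulus, assemble the segment map, split
colony groups, measure and flag footprints, apply user filters and
scoring, rank, assign destination wells and write the picklist CSV plus
a footprint table, a JSON run report and an overlay image.  Hardware
choreography (camera, transilluminator, robot handshake) is replaced by
file inputs and outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from . import colonies as ca
from . import mapping as cm
from . import screening as sc
from . import segmentation as seg
from .synthetic import PlateImage

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("platepick")

_CONFIG_KEYS = {
    "image", "fluorescence_image", "labware_center_px", "scale_mm_per_px",
    "axis_signs", "dish_diameter_range_mm", "wall_thickness_mm", "margin_mm",
    "min_diameter_mm", "segmentation", "screening", "layout", "out_dir",
    "seed", "verbosity",
}
_SEG_KEYS = {"blur_sigma_mm", "block_size_mm", "offset", "min_area_radius_mm",
             "smooth_sigma_mm", "min_peak_distance_mm"}
_SCREEN_KEYS = {"weights", "target_color", "color_mode", "color_range",
                "color_range_mode", "size_range_mm", "k"}
_RANGE_KEYS = {"h_min", "h_max", "s_min", "s_max", "v_min", "v_max"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    image: str
    labware_center_px: tuple[float, float]
    scale_mm_per_px: float
    fluorescence_image: str | None = None
    axis_signs: tuple[int, int] = (1, 1)
    dish_diameter_range_mm: tuple[float, float] = (85.0, 89.0)
    wall_thickness_mm: float = 2.0
    margin_mm: float = 2.0
    min_diameter_mm: float = 1.0
    inner_params: seg.InnerParams | None = None
    border_params: seg.BorderParams | None = None
    split_params: ca.SplitParams | None = None
    criteria: sc.ScreeningCriteria = field(default_factory=sc.ScreeningCriteria)
    layout: sc.WellLayout = field(default_factory=sc.WellLayout)
    out_dir: str = "."
    seed: int = 0
    verbosity: int = 1


@dataclass
class PipelineResult:
    picklist_path: Path
    footprints_path: Path
    report_path: Path
    overlay_path: Path
    counts: dict
    picklist: list
    footprints: list


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seg_raw = raw.pop("segmentation", {}) or {}
    if set(seg_raw) - _SEG_KEYS:
        raise ValueError(f"unknown segmentation keys: "
                         f"{sorted(set(seg_raw) - _SEG_KEYS)}")
    scr_raw = raw.pop("screening", {}) or {}
    if set(scr_raw) - _SCREEN_KEYS:
        raise ValueError(f"unknown screening keys: "
                         f"{sorted(set(scr_raw) - _SCREEN_KEYS)}")
    lay_raw = raw.pop("layout", {}) or {}
    if set(lay_raw) - {"rows", "cols"}:
        raise ValueError(f"unknown layout keys: "
                         f"{sorted(set(lay_raw) - {'rows', 'cols'})}")

    scale = float(raw["scale_mm_per_px"])
    inner = seg.InnerParams(scale_mm_per_px=scale,
                            **{k: v for k, v in seg_raw.items()
                               if k in ("blur_sigma_mm", "block_size_mm",
                                        "offset", "min_area_radius_mm")})
    split = ca.SplitParams(scale_mm_per_px=scale,
                           **{k: v for k, v in seg_raw.items()
                              if k in ("smooth_sigma_mm",
                                       "min_peak_distance_mm")})
    if "color_range" in scr_raw and scr_raw["color_range"] is not None:
        cr = scr_raw["color_range"]
        if set(cr) - _RANGE_KEYS:
            raise ValueError(f"unknown color_range keys: "
                             f"{sorted(set(cr) - _RANGE_KEYS)}")
        scr_raw["color_range"] = sc.HsvBox(**cr)
    for key in ("weights", "target_color", "size_range_mm"):
        if scr_raw.get(key) is not None:
            scr_raw[key] = tuple(scr_raw[key])
    criteria = sc.ScreeningCriteria(**scr_raw)
    layout = sc.WellLayout(**lay_raw)

    for key in ("labware_center_px", "axis_signs", "dish_diameter_range_mm"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(inner_params=inner, split_params=split,
                     border_params=seg.BorderParams(scale_mm_per_px=scale),
                     criteria=criteria, layout=layout, **raw)


def _load_image(cfg: RunConfig) -> PlateImage:
    rgb = np.asarray(Image.open(cfg.image).convert("RGB"))
    fluor = None
    if cfg.fluorescence_image:
        fluor = np.asarray(Image.open(cfg.fluorescence_image).convert("L"))
    return PlateImage(rgb, fluor, cfg.scale_mm_per_px)


def _overlay(crop: seg.CropImage, fps, selection, path) -> None:
    img = Image.fromarray(crop.rgb).convert("RGB")
    draw = ImageDraw.Draw(img)
    sel = {cid for cid, _ in selection} if selection and \
        isinstance(selection[0], tuple) else set(selection or [])
    for fp in fps:
        x, y = fp.centroid
        r = max(4.0, np.sqrt(fp.area_px / np.pi) + 2)
        color = (255, 60, 60) if fp.id in sel else (255, 220, 60)
        draw.ellipse([x - r, y - r, x + r, y + r], outline=color, width=2)
    img.save(path)


def run_pipeline(cfg: RunConfig, image: PlateImage | None = None
                 ) -> PipelineResult:
    """Execute the full detection/screening/picklist pipeline.

    ``image`` may be supplied directly (e.g. a freshly generated synthetic
    plate); otherwise it is read from ``cfg.image``.  Raises
    :class:`platepick.segmentation.DishNotFoundError` when no dish is
    detected; a run with zero colonies after filtering succeeds with an
    empty picklist and a warning.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate = image if image is not None else _load_image(cfg)
    scale = cfg.scale_mm_per_px

    geom = seg.detect_dish(plate, cfg.labware_center_px, scale,
                           cfg.dish_diameter_range_mm, cfg.wall_thickness_mm)
    crop = seg.crop_dish(plate, geom)
    inner = seg.segment_inner(crop, geom, cfg.inner_params
                              or seg.InnerParams(scale_mm_per_px=scale))
    border = seg.segment_border(crop, geom, cfg.border_params
                                or seg.BorderParams(scale_mm_per_px=scale))
    segmap = seg.build_segment_map(inner, border, geom,
                                   crop.dish_center_local)
    gray = seg.rgb_to_gray(crop.rgb)
    fps = ca.split_groups(segmap, gray, cfg.split_params
                          or ca.SplitParams(scale_mm_per_px=scale))
    ca.measure_footprints(fps, crop.rgb, crop.fluorescence, scale)
    ca.flag_pickable(fps, geom, cfg.margin_mm, scale, cfg.min_diameter_mm,
                     crop.dish_center_local)
    n_detected = len(fps)

    candidates = [fp for fp in fps if fp.pickable]
    if cfg.criteria.size_range_mm is not None:
        lo, hi = cfg.criteria.size_range_mm
        candidates = [fp for fp in candidates
                      if lo <= fp.equivalent_diameter_mm <= hi]
    if cfg.criteria.color_range is not None:
        candidates = sc.color_filter(candidates, cfg.criteria.color_range,
                                     cfg.criteria.color_range_mode)
    n_filtered = len(candidates)

    if candidates and cfg.criteria.k > 0:
        scores = sc.score_colonies(candidates, cfg.criteria)
        selection_ids = sc.rank_and_select(scores, cfg.criteria.k)
        selection = sc.assign_destinations(selection_ids, cfg.layout)
        score_by_id = {s.colony_id: s.total for s in scores}
        frame = cm.CameraFrame(cfg.labware_center_px, scale, cfg.axis_signs)
        picklist = cm.build_picklist(selection, fps, geom, frame, score_by_id)
    else:
        picklist = []
        selection = []
        if cfg.criteria.k > 0:
            log.warning("zero colonies left after filtering; "
                        "writing an empty picklist")

    picklist_path = out_dir / "picklist.csv"
    cm.write_picklist_csv(picklist, picklist_path)
    footprints_path = out_dir / "footprints.csv"
    ca.footprints_to_frame(fps).to_csv(footprints_path, index=False)
    overlay_path = out_dir / "overlay.png"
    _overlay(crop, fps, selection, overlay_path)

    counts = {
        "segments": len(segmap.records),
        "colony_segments": len(segmap.colony_ids()),
        "footprints": n_detected,
        "pickable": sum(1 for fp in fps if fp.pickable),
        "after_filters": n_filtered,
        "selected": len(picklist),
        "dish_center_px": list(geom.center_px),
        "dish_radius_px": geom.radius_px,
        "dish_offset_px": list(geom.offset_to_labware_px),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(counts, indent=1))
    for stage in ("segments", "footprints", "after_filters", "selected"):
        log.info("%s: %s", stage, counts[stage])
    return PipelineResult(picklist_path, footprints_path, report_path,
                          overlay_path, counts, picklist, fps)
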