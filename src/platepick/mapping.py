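"""Pixel-to-robot coordinate mapping and picklist CSV output.

A colony centroid c_i is known in crop-local pixels.  Its offset from the
labware centre O_lab is the vector sum of the dish-to-labware offset
(O_Pet - O_lab, from dish detection) and the colony-to-dish-centre offset
(c_i - O_Pet') measured in the crop.  The pixel offset is scaled to mm
with the camera conversion factor, converted from the image frame (y
down) to a right-handed frame (y negated) and rotated 90 degrees
anticlockwise to the robot frame; per-axis sign flags absorb the physical
mount orientation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .colonies import ColonyFootprint
from .segmentation import DishGeometry

__all__ = [
    "CameraFrame",
    "PickTarget",
    "colony_offset_pixels",
    "pixel_to_robot",
    "robot_to_pixel",
    "build_picklist",
    "write_picklist_csv",
    "read_picklist_csv",
]

PICKLIST_HEADER = ["colony_id", "dx_mm", "dy_mm", "score", "pick_order",
                   "dest_well"]


@dataclass(frozen=True)
class CameraFrame:
    """Camera calibration: labware centre, mm/px scale, axis signs."""

    labware_center_px: tuple[float, float]
    scale_mm_per_px: float
    axis_sign_flags: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be > 0")
        if any(f not in (-1, 1) for f in self.axis_sign_flags):
            raise ValueError("axis_sign_flags must be +-1")


@dataclass
class PickTarget:
    """One selected colony's robot-frame mm offset from the labware centre."""

    colony_id: int
    robot_offset_mm: tuple[float, float]
    score: float
    pick_order: int
    dest_well: str


def colony_offset_pixels(c_i: tuple[float, float],
                         o_pet_prime: tuple[float, float],
                         dish_offset_px: tuple[float, float]
                         ) -> tuple[float, float]:
    """Pixel offset of a colony from the labware centre.

    Vector sum of the dish-to-labware offset and the crop-local
    colony-to-dish-centre offset.
    """
    return (dish_offset_px[0] + (c_i[0] - o_pet_prime[0]),
            dish_offset_px[1] + (c_i[1] - o_pet_prime[1]))


def pixel_to_robot(offset_px: tuple[float, float],
                   frame: CameraFrame) -> tuple[float, float]:
    """Scale a pixel offset to mm and rotate it into the robot frame.

    The image vector (x right, y down) is scaled, converted to a
    right-handed frame by negating y, rotated 90 degrees anticlockwise
    ((u, v) -> (-v, u)), and finally multiplied by the axis sign flags.
    """
    s = frame.scale_mm_per_px
    u = offset_px[0] * s
    v = -offset_px[1] * s
    rx, ry = -v, u
    fx, fy = frame.axis_sign_flags
    return (fx * rx, fy * ry)


def robot_to_pixel(offset_mm: tuple[float, float],
                   frame: CameraFrame) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_robot`."""
    fx, fy = frame.axis_sign_flags
    rx, ry = offset_mm[0] / fx, offset_mm[1] / fy
    u, v = ry, -rx
    s = frame.scale_mm_per_px
    return (u / s, -v / s)


def build_picklist(selection: list[tuple[int, str]] | list[int],
                   footprints: list[ColonyFootprint],
                   geom: DishGeometry,
                   frame: CameraFrame,
                   scores: dict[int, float] | None = None
                   ) -> list[PickTarget]:
    """Build robot-frame pick targets for the selected colonies.

    ``selection`` is either (colony id, destination well) pairs or bare
    ids (wells left empty), in pick order.  Selected colonies must exist
    among the footprints and be flagged pickable.
    """
    by_id = {fp.id: fp for fp in footprints}
    targets = []
    for order, item in enumerate(selection, start=1):
        cid, well = item if isinstance(item, tuple) else (item, "")
        if cid not in by_id:
            raise KeyError(f"selected colony {cid} not among footprints")
        fp = by_id[cid]
        if fp.pickable is False:
            raise ValueError(f"selected colony {cid} is not pickable")
        off_px = colony_offset_pixels(fp.centroid, geom.center_local,
                                      geom.offset_to_labware_px)
        off_mm = pixel_to_robot(off_px, frame)
        score = scores.get(cid, math.nan) if scores else math.nan
        targets.append(PickTarget(cid, off_mm, score, order, well))
    return targets


def write_picklist_csv(picklist: list[PickTarget], path) -> None:
    """Write the picklist CSV (mm at 6 decimal places)."""
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(PICKLIST_HEADER)
            for t in picklist:
                w.writerow([t.colony_id,
                            f"{t.robot_offset_mm[0]:.6f}",
                            f"{t.robot_offset_mm[1]:.6f}",
                            "" if math.isnan(t.score) else f"{t.score:.6f}",
                            t.pick_order, t.dest_well])
    except OSError as exc:
        raise OSError(f"cannot write picklist to {path}: {exc}") from exc


def read_picklist_csv(path) -> list[PickTarget]:
    """Read a picklist CSV written by :func:`write_picklist_csv`."""
    targets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != PICKLIST_HEADER:
            raise ValueError(f"unexpected picklist header in {path}")
        for row in reader:
            targets.append(PickTarget(
                int(row["colony_id"]),
                (float(row["dx_mm"]), float(row["dy_mm"])),
                float(row["score"]) if row["score"] else math.nan,
                int(row["pick_order"]), row["dest_well"]))
    return targets
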