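"""Colony-level analysis: group splitting, measurement, pickability.

Multi-colony segments (touching colonies merged into one footprint by the
binarization + convex hull) are split by a local-maximum search: regional
maxima of the Gaussian-smoothed grayscale inside a segment mark individual
colony peaks, and a marker-controlled watershed on the inverted smoothed
intensity partitions the segment between them.  Footprints are then
measured (area, equivalent diameter, circular-mean HSV color, mean
fluorescence) and flagged pickable when they sit clear of the dish wall
security margin and exceed the minimum pickable diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .segmentation import DishGeometry, SegmentMap, rgb_to_gray

__all__ = [
    "ColonyFootprint",
    "SplitParams",
    "split_groups",
    "measure_footprints",
    "flag_pickable",
    "footprints_to_frame",
]


@dataclass
class ColonyFootprint:
    """One detected colony in crop-local pixel coordinates.

    The pixel mask is stored as a boolean array over the footprint's
    bounding box ``bbox = (x0, y0, x1, y1)`` (half-open) to keep dense
    plates cheap.  ``mean_hsv`` is (H in [0, 360), S, V in [0, 1]);
    ``mean_fluorescence`` is on the 8-bit scale and None when no
    fluorescence image was supplied.
    """

    id: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    centroid: tuple[float, float]           # (x, y), crop-local
    area_px: int
    parent_segment: int = -1
    n_colonies_in_parent_segment: int = 1
    area_mm2: float | None = None
    equivalent_diameter_mm: float | None = None
    mean_hsv: tuple[float, float, float] | None = None
    mean_fluorescence: float | None = None
    pickable: bool | None = None

    def mask_pixels(self):
        """(rows, cols) indices of the mask in crop coordinates."""
        ys, xs = np.nonzero(self.mask)
        return ys + self.bbox[1], xs + self.bbox[0]

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bbox
        xi, yi = int(round(x)), int(round(y))
        if not (x0 <= xi < x1 and y0 <= yi < y1):
            return False
        return bool(self.mask[yi - y0, xi - x0])


@dataclass(frozen=True)
class SplitParams:
    """Local-maximum group-splitting parameters (lengths in mm)."""

    scale_mm_per_px: float = 0.1
    smooth_sigma_mm: float = 0.3
    min_peak_distance_mm: float = 0.8
    #: Minimum height (gray levels) of a cell's peak over the cell's own
    #: intensity floor.  Rejects maxima seeded on agar inside oversized
    #: segments (convex hulls of colony chains cover agar between
    #: colonies) while keeping even dim, small colonies, whose smoothed
    #: dome still rises well above this.
    min_prominence: float = 8.0

    @property
    def sigma_px(self) -> float:
        return self.smooth_sigma_mm / self.scale_mm_per_px

    @property
    def d_min_px(self) -> int:
        return max(1, int(round(self.min_peak_distance_mm / self.scale_mm_per_px)))


def _watershed_with_markers(patch, mask, peaks):
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = k
    return watershed(-patch, markers, mask=mask)


def _watershed_prominent(patch, mask, peaks, min_prominence):
    """Marker-controlled watershed keeping only prominent peaks.

    A first watershed partitions the mask between all candidate maxima;
    cells whose peak rises less than ``min_prominence`` over the cell's
    own 5th-percentile floor are dropped (they are agar pockets inside an
    oversized segment) and the watershed is rerun with the survivors so
    the children still partition the parent exactly.
    """
    ws = _watershed_with_markers(patch, mask, peaks)
    keep = []
    for k, (py, px) in enumerate(peaks, start=1):
        cell = patch[ws == k]
        if len(cell) and patch[py, px] - np.percentile(cell, 5) >= min_prominence:
            keep.append(k)
    if len(keep) == 0:
        vals = patch[tuple(peaks.T)]
        keep = [int(np.argmax(vals)) + 1]
    if len(keep) == 1:
        return mask.astype(np.int32), 1
    if len(keep) < len(peaks):
        ws = _watershed_with_markers(patch, mask, peaks[np.array(keep) - 1])
    return ws, len(keep)


def split_groups(segmap: SegmentMap, gray_crop: np.ndarray,
                 p: SplitParams | None = None) -> list[ColonyFootprint]:
    """Split multi-colony segments at grayscale local maxima.

    For each "colonies" segment the regional maxima of the smoothed
    grayscale inside the segment are found (minimum separation
    ``p.min_peak_distance_mm``); with two or more maxima the segment is
    divided by marker-controlled watershed and its sublabel updated to
    "k colonies".  Child masks always partition the parent segment.
    """
    p = p or SplitParams()
    if gray_crop.ndim == 3:
        gray_crop = rgb_to_gray(gray_crop)
    if gray_crop.shape != segmap.labels.shape:
        raise ValueError("grayscale crop must be aligned with the segment map")
    smoothed = ndi.gaussian_filter(gray_crop.astype(float), p.sigma_px)

    footprints: list[ColonyFootprint] = []
    next_id = 0
    objs = ndi.find_objects(segmap.labels)
    for sid in segmap.colony_ids():
        sl = objs[sid - 1]
        if sl is None:
            continue
        mask = segmap.labels[sl] == sid
        patch = smoothed[sl]
        peaks = peak_local_max(patch, min_distance=p.d_min_px,
                               exclude_border=False,
                               labels=mask.astype(np.int32))
        y0, x0 = sl[0].start, sl[1].start
        if len(peaks) >= 2:
            ws, n_children = _watershed_prominent(patch, mask, peaks,
                                                  p.min_prominence)
        else:
            ws = mask.astype(np.int32)
            n_children = 1
        rec = segmap.records[sid]
        rec.n_colonies = n_children
        rec.sublabel = "1 colony" if n_children == 1 else f"{n_children} colonies"
        for k in range(1, n_children + 1):
            child = ws == k
            if not child.any():
                continue
            ys, xs = np.nonzero(child)
            cy0, cy1 = ys.min(), ys.max() + 1
            cx0, cx1 = xs.min(), xs.max() + 1
            footprints.append(ColonyFootprint(
                id=next_id,
                bbox=(x0 + cx0, y0 + cy0, x0 + cx1, y0 + cy1),
                mask=child[cy0:cy1, cx0:cx1].copy(),
                centroid=(x0 + xs.mean(), y0 + ys.mean()),
                area_px=int(child.sum()),
                parent_segment=sid,
                n_colonies_in_parent_segment=n_children,
            ))
            next_id += 1
    return footprints


def _circular_hue_mean(h_deg: np.ndarray, weights: np.ndarray | None = None
                       ) -> float:
    """Unit-vector mean of hue angles in degrees, result in [0, 360)."""
    a = np.deg2rad(h_deg)
    w = np.ones_like(a) if weights is None else weights
    s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    if s == 0 and c == 0:
        return 0.0
    return float(np.rad2deg(math.atan2(s, c)) % 360.0)


def measure_footprints(fps: list[ColonyFootprint], rgb_crop: np.ndarray,
                       fluor_crop: np.ndarray | None,
                       scale_mm_per_px: float) -> list[ColonyFootprint]:
    """Measure size, color and fluorescence of each footprint in place.

    area_mm2 = area_px * scale^2; equivalent_diameter_mm is the diameter
    of the circle of equal area.  Hue is averaged circularly (unit-vector
    mean, saturation-weighted) to avoid the 0/360 wrap artifact.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be > 0")
    hsv = skcolor.rgb2hsv(rgb_crop)
    for fp in fps:
        if fp.area_px == 0 or not fp.mask.any():
            raise ValueError(f"footprint {fp.id} has an empty mask")
        ys, xs = fp.mask_pixels()
        fp.area_mm2 = fp.area_px * scale_mm_per_px ** 2
        fp.equivalent_diameter_mm = 2.0 * math.sqrt(fp.area_mm2 / math.pi)
        h = hsv[ys, xs, 0] * 360.0
        s = hsv[ys, xs, 1]
        v = hsv[ys, xs, 2]
        sw = s if s.sum() > 0 else None
        fp.mean_hsv = (_circular_hue_mean(h, sw), float(s.mean()),
                       float(v.mean()))
        if fluor_crop is not None:
            fp.mean_fluorescence = float(fluor_crop[ys, xs].mean())
    return fps


def flag_pickable(fps: list[ColonyFootprint], geom: DishGeometry,
                  margin_mm: float, scale_mm_per_px: float,
                  min_diameter_mm: float = 1.0,
                  dish_center_local: tuple[float, float] | None = None
                  ) -> list[ColonyFootprint]:
    """Flag colonies safe for robotic picking.

    Pickable means the centroid lies at least ``margin_mm`` (plus the wall
    thickness) inside the detected dish radius, and the equivalent
    diameter is at least ``min_diameter_mm`` (tiny colonies incur large
    relative positioning error at pick time).
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if dish_center_local is None:
        dish_center_local = geom.center_local
    r_max = geom.radius_px - geom.wall_px - margin_mm / scale_mm_per_px
    for fp in fps:
        d = math.hypot(fp.centroid[0] - dish_center_local[0],
                       fp.centroid[1] - dish_center_local[1])
        diam = fp.equivalent_diameter_mm
        if diam is None:
            diam = 2.0 * math.sqrt(fp.area_px * scale_mm_per_px ** 2 / math.pi)
        fp.pickable = bool(d <= r_max and diam >= min_diameter_mm)
    return fps


def footprints_to_frame(fps: list[ColonyFootprint]) -> pd.DataFrame:
    """Tabulate measured footprints (one row per colony) for CSV export."""
    rows = []
    for fp in fps:
        h, s, v = fp.mean_hsv if fp.mean_hsv else (np.nan, np.nan, np.nan)
        rows.append({
            "id": fp.id,
            "x_px": fp.centroid[0], "y_px": fp.centroid[1],
            "area_px": fp.area_px,
            "area_mm2": fp.area_mm2,
            "equivalent_diameter_mm": fp.equivalent_diameter_mm,
            "hue": h, "saturation": s, "value": v,
            "mean_fluorescence": (np.nan if fp.mean_fluorescence is None
                                  else fp.mean_fluorescence),
            "n_colonies_in_parent_segment": fp.n_colonies_in_parent_segment,
            "pickable": fp.pickable,
        })
    cols = ["id", "x_px", "y_px", "area_px", "area_mm2",
            "equivalent_diameter_mm", "hue", "saturation", "value",
            "mean_fluorescence", "n_colonies_in_parent_segment", "pickable"]
    return pd.DataFrame(rows, columns=cols)
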