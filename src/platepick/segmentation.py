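"""Classical plate segmentation: dish detection, cropping, binarization.

The pipeline mirrors the standard colony-counter recipe: locate the dish
with a circular Hough transform, crop its bounding box, binarize the inner
agar disc with Gaussian blurring + adaptive Gaussian thresholding and
regularize each component to its convex hull (Sklansky), and treat the
wall annulus separately (speckle noise -> Canny -> morphological
filtering) so colonies straddling the unpickable margin are still found
while the plastic wall edge is suppressed.

Pixel coordinates are (x = column, y = row), origin top-left, half-open
bounds.  All default length parameters are expressed in millimetres and
converted with the camera scale so they are resolution independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, transform

from .synthetic import PlateImage

__all__ = [
    "DishGeometry",
    "SegmentMap",
    "SegmentRecord",
    "InnerParams",
    "BorderParams",
    "CropImage",
    "DishNotFoundError",
    "detect_dish",
    "crop_dish",
    "segment_inner",
    "segment_border",
    "build_segment_map",
    "rgb_to_gray",
]

#: Segment ids reserved for the two background segments.
OUT_OF_PLATE_ID = 1
AGAR_ID = 2


class DishNotFoundError(RuntimeError):
    """No circle within the configured diameter range was detected."""


@dataclass
class DishGeometry:
    """Detected Petri-dish geometry in full-image pixel coordinates."""

    center_px: tuple[float, float]          # O_Pet (x, y)
    radius_px: float                        # outer wall radius
    bbox: tuple[int, int, int, int]         # (x0, y0, x1, y1), half-open
    offset_to_labware_px: tuple[float, float]   # O_Pet - O_lab
    wall_px: float = 0.0                    # wall thickness in px

    @property
    def inner_radius_px(self) -> float:
        return self.radius_px - self.wall_px

    @property
    def crop_origin(self) -> tuple[int, int]:
        return (self.bbox[0], self.bbox[1])

    @property
    def center_local(self) -> tuple[float, float]:
        """Dish centre O_Pet' in crop-local coordinates."""
        return (self.center_px[0] - self.bbox[0],
                self.center_px[1] - self.bbox[1])


@dataclass
class SegmentRecord:
    """Category record of one segment of a :class:`SegmentMap`."""

    id: int
    supercategory: str          # "background" | "colonies"
    sublabel: str               # "out of plate", "0 colonies", "1 colony", ...
    n_colonies: int = 0


@dataclass
class SegmentMap:
    """Per-pixel segment ids over a crop plus per-segment categories."""

    labels: np.ndarray                      # (H, W) int32, every pixel labelled
    records: dict[int, SegmentRecord] = field(default_factory=dict)

    def colony_ids(self) -> list[int]:
        return [r.id for r in self.records.values()
                if r.supercategory == "colonies"]

    def is_partition(self) -> bool:
        ids = set(np.unique(self.labels).tolist())
        return ids == set(self.records.keys())


@dataclass(frozen=True)
class InnerParams:
    """Inner-disc binarization parameters (lengths in mm)."""

    scale_mm_per_px: float = 0.1
    blur_sigma_mm: float = 0.15
    block_size_mm: float = 6.0
    offset: float = -4.0        # local threshold = gaussian mean - offset
    min_area_radius_mm: float = 0.3

    @property
    def blur_sigma_px(self) -> float:
        return self.blur_sigma_mm / self.scale_mm_per_px

    @property
    def block_size_px(self) -> int:
        b = int(round(self.block_size_mm / self.scale_mm_per_px))
        return b + 1 if b % 2 == 0 else b

    @property
    def min_area_px(self) -> int:
        r = self.min_area_radius_mm / self.scale_mm_per_px
        return max(1, int(round(np.pi * r * r)))


@dataclass(frozen=True)
class BorderParams:
    """Annulus (wall region) treatment parameters."""

    scale_mm_per_px: float = 0.1
    speckle_amplitude: float = 0.2      # multiplicative uniform noise +-20%
    canny_sigma_px: float = 1.0
    # Hysteresis thresholds as fractions of the annulus intensity range:
    # colony edges over agar clear the high threshold while speckle noise
    # on bare agar stays below the low one.  The wall's own much stronger
    # circular edges are removed geometrically, not by thresholding.
    canny_low: float = 0.1
    canny_high: float = 0.3
    opening_radius_mm: float = 0.4      # top-hat / opening structuring disc
    max_blob_radius_mm: float = 3.0     # larger blobs are wall remnants
    wall_edge_clear_px: float = 3.0     # edge pixels this close to a wall
                                        # circle are discarded
    wall_foot_clear_px: float = 6.0     # clearance inside the inner wall
                                        # edge, where the brightness ramp
                                        # begins and speckle amplifies it
    overlap_mm: float = 2.0             # band inside the inner disc also
                                        # searched (colonies straddling it);
                                        # must exceed wall_foot_clear_px
                                        # in mm for the band to be nonempty
    seed: int = 0


@dataclass
class CropImage:
    """Dish bounding-box crop with provenance back to the full image."""

    rgb: np.ndarray
    origin: tuple[int, int]                 # (x0, y0) of the crop
    dish_center_local: tuple[float, float]  # O_Pet'
    fluorescence: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luminance grayscale as float in [0, 255]."""
    return rgb.astype(float) @ np.array([0.299, 0.587, 0.114])


def _hough_best(edges: np.ndarray, radii: np.ndarray):
    h = transform.hough_circle(edges, radii)
    accums, cxs, cys, rads = transform.hough_circle_peaks(
        h, radii, total_num_peaks=1)
    if len(accums) == 0:
        return None
    return float(accums[0]), float(cxs[0]), float(cys[0]), float(rads[0])


def _kasa_circle_fit(x: np.ndarray, y: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit to edge points."""
    a = np.column_stack([x, y, np.ones_like(x)]).astype(float)
    b = x.astype(float) ** 2 + y.astype(float) ** 2
    (d, e, f), *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = d / 2.0, e / 2.0
    r = math.sqrt(max(f + cx * cx + cy * cy, 0.0))
    return cx, cy, r


#: Minimum wall-plateau to background contrast (gray levels) for a
#: radial profile to count as a genuine dish wall.
_MIN_WALL_CONTRAST = 20.0


def _snap_outer_radius(gray: np.ndarray, center: tuple[float, float],
                       r_hough: float, wall_px: float) -> float | None:
    """Snap a Hough radius to the outer wall edge.

    Computes the azimuthal mean intensity profile in a band covering both
    possible wall edges and returns the outermost half-height crossing
    (wall plateau -> dark background), linearly interpolated to subpixel.
    Returns None when the profile shows no wall-like contrast — the
    physical sanity check that separates a real dish from a spurious
    Hough peak.
    """
    lo = max(1.0, r_hough - 4.0)
    hi = min(r_hough + wall_px + 6.0,
             min(center[0], center[1],
                 gray.shape[1] - center[0], gray.shape[0] - center[1]) - 1)
    if hi <= lo + 2:
        return None
    yy, xx = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    d = np.hypot(xx - center[0], yy - center[1])
    band = (d >= lo) & (d < hi)
    bins = (d[band] - lo).astype(int)
    n_bins = int(hi - lo) + 1
    sums = np.bincount(bins, weights=gray[band], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    prof = sums / np.maximum(counts, 1)
    bg = prof[-3:].mean()
    wall = prof.max()
    if wall - bg < _MIN_WALL_CONTRAST:
        return None
    half = (wall + bg) / 2.0
    above = np.flatnonzero(prof >= half)
    if len(above) == 0:
        return None
    i = above[-1]
    if i + 1 < len(prof) and prof[i] != prof[i + 1]:
        frac = (prof[i] - half) / (prof[i] - prof[i + 1])
    else:
        frac = 0.5
    return lo + i + frac


def detect_dish(image: PlateImage | np.ndarray,
                labware_center_px: tuple[float, float],
                scale_mm_per_px: float = 0.1,
                diameter_range_mm: tuple[float, float] = (85.0, 89.0),
                wall_thickness_mm: float = 2.0,
                min_accum: float = 0.25) -> DishGeometry:
    """Locate the dish wall circle and its offset to the labware centre.

    A coarse circular Hough transform on a 4x-downsampled edge map finds
    the approximate circle; a full-resolution Hough pass over a narrow
    radius band refines it.  Raises :class:`DishNotFoundError` when no
    circle in the configured diameter range receives sufficient support.
    """
    rgb = image.rgb if isinstance(image, PlateImage) else image
    gray = rgb_to_gray(rgb) if rgb.ndim == 3 else rgb.astype(float)
    r_lo = diameter_range_mm[0] / 2.0 / scale_mm_per_px
    r_hi = diameter_range_mm[1] / 2.0 / scale_mm_per_px

    f = 4
    small = gray[::f, ::f]
    edges = feature.canny(small, sigma=2.0)
    radii = np.arange(int(r_lo / f) - 2, int(np.ceil(r_hi / f)) + 3)
    best = _hough_best(edges, radii)
    if best is None:
        raise DishNotFoundError("no dish found: empty Hough accumulator")
    _, cx4, cy4, r4 = best

    edges_all = feature.canny(gray, sigma=2.0)
    # Restrict votes to a band around the coarse circle.
    yy, xx = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    d = np.hypot(xx - cx4 * f, yy - cy4 * f)
    edges_band = edges_all & (np.abs(d - r4 * f) < 3 * f)
    radii_fine = np.arange(max(int(r_lo) - 2, int(r4 * f) - 2 * f),
                           min(int(np.ceil(r_hi)) + 3, int(r4 * f) + 2 * f))
    best = _hough_best(edges_band, radii_fine)
    if best is None:
        raise DishNotFoundError("no dish found: refinement failed")
    accum, cx, cy, r = best
    if accum < min_accum:
        raise DishNotFoundError(
            f"no dish found: peak support {accum:.2f} below {min_accum}")
    # The Hough peak may sit on the inner wall edge (agar/wall contrast is
    # comparable to wall/background) and is quantized to whole pixels;
    # snap the radius to the outer edge by radial intensity profile, then
    # iterate a least-squares circle fit to the outer-edge pixels.
    wall_px = wall_thickness_mm / scale_mm_per_px
    r = _snap_outer_radius(gray, (cx, cy), r, wall_px)
    if r is None:
        raise DishNotFoundError(
            "no dish found: no wall-like radial intensity profile")
    for _ in range(2):
        dd = np.hypot(xx - cx, yy - cy)
        pts = np.argwhere(edges_all & (np.abs(dd - r) < 4))
        if len(pts) < 50:
            break
        cx, cy, r_fit = _kasa_circle_fit(pts[:, 1], pts[:, 0])
        r_fit = _snap_outer_radius(gray, (cx, cy), r_fit, wall_px)
        if r_fit is None:
            break
        r = r_fit

    n_rows, n_cols = gray.shape
    x0 = max(int(np.floor(cx - r)), 0)
    y0 = max(int(np.floor(cy - r)), 0)
    x1 = min(int(np.ceil(cx + r)) + 1, n_cols)
    y1 = min(int(np.ceil(cy + r)) + 1, n_rows)
    offset = (cx - labware_center_px[0], cy - labware_center_px[1])
    return DishGeometry((cx, cy), r, (x0, y0, x1, y1), offset,
                        wall_px=wall_thickness_mm / scale_mm_per_px)


def crop_dish(image: PlateImage | np.ndarray, geom: DishGeometry) -> CropImage:
    """Crop the dish bounding box; records origin and local dish centre."""
    rgb = image.rgb if isinstance(image, PlateImage) else image
    fluor = image.fluorescence if isinstance(image, PlateImage) else None
    x0, y0, x1, y1 = geom.bbox
    x0 = max(x0, 0); y0 = max(y0, 0)
    x1 = min(x1, rgb.shape[1]); y1 = min(y1, rgb.shape[0])
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate dish bounding box {geom.bbox}")
    local = (geom.center_px[0] - x0, geom.center_px[1] - y0)
    return CropImage(rgb[y0:y1, x0:x1], (x0, y0), local,
                     fluor[y0:y1, x0:x1] if fluor is not None else None)


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(xx - center[0], yy - center[1]) <= radius


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def _hull_components(mask: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Replace every connected component by its convex hull (Sklansky).

    Overlapping hulls merge neighbouring components, so the operation is
    iterated to a fixpoint: in the result every component equals its own
    convex hull.
    """
    current = mask
    for _ in range(max_iter):
        out = np.zeros_like(current)
        labels = measure.label(current, connectivity=2)
        for region in measure.regionprops(labels):
            y0, x0, y1, x1 = region.bbox
            out[y0:y1, x0:x1] |= region.image_convex
        if np.array_equal(out, current):
            break
        current = out
    return current


def segment_inner(crop: CropImage, geom: DishGeometry,
                  p: InnerParams | None = None) -> np.ndarray:
    """Binarize colonies in the inner agar disc.

    Gaussian blur, adaptive Gaussian thresholding (foreground where the
    blurred intensity exceeds the local Gaussian-weighted mean minus
    ``p.offset``), small-object removal, then per-component convex hulls.
    Operates strictly inside the inner disc (wall excluded).
    """
    p = p or InnerParams()
    gray = rgb_to_gray(crop.rgb)
    blurred = ndi.gaussian_filter(gray, p.blur_sigma_px)
    thresh = filters.threshold_local(blurred, block_size=p.block_size_px,
                                     method="gaussian", offset=p.offset)
    fg = blurred > thresh
    inner = _disc_mask(gray.shape, crop.dish_center_local,
                       geom.inner_radius_px - 1.0)
    fg &= inner
    fg = _drop_small(fg, p.min_area_px)
    return _hull_components(fg) & inner


def segment_border(crop: CropImage, geom: DishGeometry,
                   p: BorderParams | None = None) -> np.ndarray:
    """Find colony-like blobs in the wall annulus, suppressing the wall.

    Deterministic multiplicative speckle noise breaks the continuous wall
    edge, Canny finds the remaining closed contours, which are sealed,
    hole-filled and eroded; a final top-hat subtraction (equivalently a
    morphological opening) removes thin wall arcs, and implausibly large
    blobs (wall remnants) are dropped.  The result is confined to the
    annulus between the inner disc and the crop bounds.
    """
    p = p or BorderParams()
    gray = rgb_to_gray(crop.rgb)
    rng = np.random.default_rng(p.seed)
    speckled = gray * (1.0 + rng.uniform(-p.speckle_amplitude,
                                         p.speckle_amplitude, gray.shape))
    overlap_px = p.overlap_mm / p.scale_mm_per_px
    annulus = ~_disc_mask(gray.shape, crop.dish_center_local,
                          geom.inner_radius_px - overlap_px)
    band = speckled[annulus]
    span = float(band.max() - band.min()) if band.size else 1.0
    edges = feature.canny(speckled, sigma=p.canny_sigma_px,
                          low_threshold=p.canny_low * span,
                          high_threshold=p.canny_high * span,
                          use_quantiles=False)
    edges &= annulus
    # Suppress the wall itself: the two circular wall edges (at the
    # detected outer radius and one wall thickness inside it) and the
    # bright wall interior, where an agar-grown colony cannot show
    # through the opaque plastic.  Colony blobs straddling the margin
    # keep their non-concentric contours in the agar band.
    yy, xx = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    d = np.hypot(xx - crop.dish_center_local[0],
                 yy - crop.dish_center_local[1])
    edges &= np.abs(d - geom.radius_px) > p.wall_edge_clear_px
    edges &= d < geom.inner_radius_px - p.wall_foot_clear_px
    sealed = morphology.closing(edges, morphology.disk(1))
    filled = ndi.binary_fill_holes(sealed)
    eroded = morphology.erosion(filled, morphology.disk(1))
    r_open = max(1, int(round(p.opening_radius_mm / p.scale_mm_per_px)))
    tophat = morphology.white_tophat(eroded, morphology.disk(r_open))
    blobs = eroded & ~tophat
    # Colony contours cut by the band limits never close, so hole filling
    # alone misses them; thickened edge arcs recover those fragments.
    arcs = morphology.closing(edges, morphology.disk(2))
    min_area = max(1, int(round(
        np.pi * (0.3 / p.scale_mm_per_px) ** 2)))
    blobs = _drop_small(blobs | arcs, min_area)
    max_area = np.pi * (p.max_blob_radius_mm / p.scale_mm_per_px) ** 2
    labels = measure.label(blobs, connectivity=2)
    for region in measure.regionprops(labels):
        if region.area > max_area:
            blobs[labels == region.label] = False
    return blobs & annulus


def build_segment_map(inner_mask: np.ndarray, border_mask: np.ndarray,
                      geom: DishGeometry,
                      dish_center_local: tuple[float, float] | None = None
                      ) -> SegmentMap:
    """Assemble the category-labelled segment map over the crop.

    Foreground components (union of the inner and border masks) become
    "colonies" segments with the initial sublabel "1 colony" (revised by
    group splitting); remaining pixels inside the dish circle form the
    "0 colonies" agar segment; pixels outside it the "out of plate" one.
    """
    if inner_mask.shape != border_mask.shape:
        raise ValueError("inner and border masks must share the crop shape")
    fg = inner_mask | border_mask
    if dish_center_local is None:
        x0, y0 = geom.crop_origin
        dish_center_local = (geom.center_px[0] - x0, geom.center_px[1] - y0)
    inside = _disc_mask(fg.shape, dish_center_local, geom.radius_px)

    comp = measure.label(fg, connectivity=2)
    labels = np.full(fg.shape, OUT_OF_PLATE_ID, dtype=np.int32)
    labels[inside] = AGAR_ID
    labels[comp > 0] = comp[comp > 0] + AGAR_ID

    records = {
        OUT_OF_PLATE_ID: SegmentRecord(OUT_OF_PLATE_ID, "background",
                                       "out of plate"),
        AGAR_ID: SegmentRecord(AGAR_ID, "background", "0 colonies"),
    }
    for cid in range(1, comp.max() + 1):
        sid = cid + AGAR_ID
        records[sid] = SegmentRecord(sid, "colonies", "1 colony", 1)
    return SegmentMap(labels, records)
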