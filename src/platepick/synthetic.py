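"""Synthetic Petri-dish plate generator with exhaustive ground truth.

Renders an 8-bit RGB photograph of a circular dish (bright plastic wall,
agar fill) on a dark background, populated with roughly circular colonies
drawn as truncated Gaussian intensity domes, plus optional touching colony
groups, non-colony specks, a mild linear illumination gradient and Gaussian
sensor noise.  An optional co-registered fluorescence channel renders each
colony as a flat disc at its assigned mean intensity.

Every generated object is recorded in a :class:`GroundTruthPlate` so that
downstream detection, screening and coordinate mapping can be validated
without any external data.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PlateParams",
    "BenchmarkParams",
    "DishTruth",
    "GroundTruthPlate",
    "PlateImage",
    "PlacementError",
    "generate_plate",
    "generate_benchmark",
    "benchmark_v1",
    "write_ground_truth",
    "read_ground_truth",
]

# Fraction of the agar area colonies are allowed to cover in total.  On
# crowded plates the per-colony radius upper bound shrinks so that this cap
# holds; this emulates nutrient competition (dense plates grow small
# colonies) and keeps rejection-sampling placement feasible.
_COVERAGE_CAP = 0.25

# Fixed render palette (8-bit RGB).
_BG_COLOR = np.array([28.0, 28.0, 30.0])
_WALL_COLOR = np.array([205.0, 205.0, 200.0])
_AGAR_COLOR = np.array([105.0, 95.0, 70.0])
_ARTIFACT_COLOR = np.array([240.0, 240.0, 240.0])
_FLUOR_BG = 8.0

#: Default colony phenotypes: (RGB, mixing fraction).  A whitish and a
#: bluish phenotype, mirroring blue/white screening plates.
DEFAULT_PHENOTYPES = (((235, 231, 222), 0.5), ((120, 150, 215), 0.5))

#: Default fluorescence levels: (mean 8-bit intensity, mixing fraction);
#: a bright reporter strain mixed with a dim negative control.
DEFAULT_FLUOR_LEVELS = ((200.0, 0.5), (30.0, 0.5))


class PlacementError(RuntimeError):
    """Raised when colonies cannot be placed within the retry budget."""


@dataclass(frozen=True)
class PlateParams:
    """Parameters of one synthetic plate.

    Lengths are millimetres unless the name says px.  ``dish_center_px`` is
    (x, y) with x = column, y = row, origin at the top-left pixel corner.
    """

    image_size_px: int = 1000
    dish_outer_diameter_mm: float = 87.0
    dish_center_px: tuple[float, float] | None = None
    scale_mm_per_px: float = 0.1
    n_colonies: int = 100
    group_fraction: float = 0.0
    border_fraction: float = 0.0
    artifact_count: int = 0
    color_phenotypes: tuple = DEFAULT_PHENOTYPES
    fluorescence_levels: tuple | None = DEFAULT_FLUOR_LEVELS
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.0
    colony_radius_range_mm: tuple[float, float] = (0.6, 2.5)
    wall_thickness_mm: float = 2.0
    margin_mm: float = 2.0
    min_pick_diameter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        for name in ("group_fraction", "border_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be > 0")
        rmin, rmax = self.colony_radius_range_mm
        if not 0 < rmin <= rmax:
            raise ValueError("colony_radius_range_mm must be 0 < min <= max")
        cx, cy = self.center_px
        r = self.outer_radius_px
        n = self.image_size_px
        if cx - r < 0 or cy - r < 0 or cx + r > n or cy + r > n:
            raise ValueError("dish does not fit inside the image")

    @property
    def center_px(self) -> tuple[float, float]:
        if self.dish_center_px is not None:
            return self.dish_center_px
        c = self.image_size_px / 2.0
        return (c, c)

    @property
    def outer_radius_px(self) -> float:
        return self.dish_outer_diameter_mm / 2.0 / self.scale_mm_per_px

    @property
    def inner_radius_px(self) -> float:
        return self.outer_radius_px - self.wall_thickness_mm / self.scale_mm_per_px

    @property
    def inner_radius_mm(self) -> float:
        return self.dish_outer_diameter_mm / 2.0 - self.wall_thickness_mm


@dataclass(frozen=True)
class DishTruth:
    """True dish geometry of a synthetic plate (pixel coordinates)."""

    center_px: tuple[float, float]
    outer_radius_px: float
    inner_radius_px: float


@dataclass
class PlateImage:
    """An RGB plate photograph plus optional fluorescence channel."""

    rgb: np.ndarray                      # (H, W, 3) uint8
    fluorescence: np.ndarray | None = None   # (H, W) uint8
    scale_mm_per_px: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class GroundTruthPlate:
    """Exhaustive per-object ground truth for one synthetic plate.

    ``colonies`` columns: id, x_px, y_px, x_mm, y_mm (mm offsets from the
    true dish centre, image axes), radius_mm, phenotype, color_r/g/b,
    fluorescence, group_id (-1 for singles), pickable (bool).
    ``artifacts`` columns: id, x_px, y_px, radius_mm.
    """

    colonies: pd.DataFrame
    artifacts: pd.DataFrame
    dish: DishTruth
    params: PlateParams

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def n_pickable(self) -> int:
        return int(self.colonies["pickable"].sum()) if len(self.colonies) else 0


_COLONY_COLS = [
    "id", "x_px", "y_px", "x_mm", "y_mm", "radius_mm", "phenotype",
    "color_r", "color_g", "color_b", "fluorescence", "group_id", "pickable",
]
_ARTIFACT_COLS = ["id", "x_px", "y_px", "radius_mm"]


def _sample_radii(params: PlateParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample colony radii (mm), shrinking the upper bound with crowding."""
    rmin, rmax = params.colony_radius_range_mm
    if n == 0:
        return np.empty(0)
    agar_area = math.pi * params.inner_radius_mm ** 2
    budget = _COVERAGE_CAP * agar_area / n
    # For r ~ U(rmin, rhi): E[pi r^2] = pi (rmin^2 + rmin*rhi + rhi^2) / 3.
    disc = 12.0 * budget / math.pi - 3.0 * rmin ** 2
    rhi = rmin if disc <= rmin ** 2 else (-rmin + math.sqrt(disc)) / 2.0
    rhi = float(np.clip(rhi, rmin, rmax))
    return rng.uniform(rmin, rhi, size=n)


def _place_colonies(params: PlateParams, radii_mm: np.ndarray,
                    rng: np.random.Generator):
    """Rejection-sample colony centres; returns (x_px, y_px, group_id).

    Non-groupmates never overlap; groupmates touch (centre distance below
    the sum of radii).  A shared retry budget of 10,000 rejections guards
    against infeasible requests.
    """
    n = len(radii_mm)
    scale = params.scale_mm_per_px
    cx, cy = params.center_px
    r_in = params.inner_radius_px
    margin_px = params.margin_mm / scale
    radii_px = radii_mm / scale

    n_border = int(round(params.border_fraction * n))
    n_grouped = int(round(params.group_fraction * n))
    if n_grouped == 1:
        n_grouped = 0
    # Group sizes: pairs, with one triple when the grouped count is odd.
    group_sizes: list[int] = []
    rem = n_grouped
    while rem >= 2:
        size = 3 if (rem % 2 == 1 or (rem >= 5 and rng.random() < 0.2)) else 2
        size = min(size, rem)
        group_sizes.append(size)
        rem -= size

    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    gids = np.full(n, -1, dtype=int)
    budget = [10_000]

    def collides(x, y, r_px, ignore=()):
        placed = np.flatnonzero(~np.isnan(xs))
        if len(placed) == 0:
            return False
        keep = np.setdiff1d(placed, np.asarray(ignore, dtype=int),
                            assume_unique=False)
        if len(keep) == 0:
            return False
        d2 = (xs[keep] - x) ** 2 + (ys[keep] - y) ** 2
        lim = (radii_px[keep] + r_px) * 1.02
        return bool(np.any(d2 < lim ** 2))

    def draw_center(r_px, dist_lo, dist_hi):
        # Uniform over the annulus [dist_lo, dist_hi] from the dish centre.
        lo2, hi2 = dist_lo ** 2, dist_hi ** 2
        rad = math.sqrt(rng.uniform(lo2, hi2))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        return cx + rad * math.cos(ang), cy + rad * math.sin(ang)

    def place(i, dist_lo, dist_hi, ignore=()):
        r_px = radii_px[i]
        hi = min(dist_hi, r_in - r_px - 1.0)
        lo = min(dist_lo, max(0.0, hi))
        while True:
            x, y = draw_center(r_px, lo, hi)
            if not collides(x, y, r_px, ignore):
                xs[i], ys[i] = x, y
                return
            budget[0] -= 1
            if budget[0] <= 0:
                raise PlacementError(
                    f"could not place colony {i}: retry budget exhausted "
                    f"(n={n}, dish inner radius {r_in:.0f} px)")

    order = list(range(n))
    # Border colonies first (inside the unpickable margin), then groups,
    # then remaining singles anywhere in the dish.
    idx = 0
    for _ in range(min(n_border, n)):
        i = order[idx]; idx += 1
        place(i, max(0.0, r_in - margin_px), r_in - radii_px[i] - 1.0)
    gid = 0
    for size in group_sizes:
        if idx + size > n:
            break
        members = order[idx:idx + size]
        idx += size
        anchor = members[0]
        place(anchor, 0.0, r_in - radii_px[anchor] - 1.0)
        gids[anchor] = gid
        for j in members[1:]:
            r_px = radii_px[j]
            while True:
                k = members[0] if j == members[1] else rng.choice(members[:members.index(j)])
                base = radii_px[k] + r_px
                d = rng.uniform(0.72, 0.92) * base
                ang = rng.uniform(0.0, 2.0 * math.pi)
                x = xs[k] + d * math.cos(ang)
                y = ys[k] + d * math.sin(ang)
                inside = math.hypot(x - cx, y - cy) <= r_in - r_px - 1.0
                if inside and not collides(x, y, r_px, ignore=members):
                    xs[j], ys[j] = x, y
                    gids[j] = gid
                    break
                budget[0] -= 1
                if budget[0] <= 0:
                    raise PlacementError("group placement retry budget exhausted")
        gid += 1
    while idx < n:
        i = order[idx]; idx += 1
        place(i, 0.0, r_in - radii_px[i] - 1.0)
    return xs, ys, gids


def _mix_choice(rng: np.random.Generator, options: tuple, n: int) -> np.ndarray:
    fracs = np.array([f for _, f in options], dtype=float)
    fracs = fracs / fracs.sum()
    return rng.choice(len(options), size=n, p=fracs)


def _render_domes(canvas: np.ndarray, xs, ys, radii_px, colors, agar):
    """Max-blend truncated Gaussian domes onto a float RGB canvas."""
    h, w = canvas.shape[:2]
    for x, y, r, col in zip(xs, ys, radii_px, colors):
        x0 = max(int(math.floor(x - r)) - 1, 0)
        y0 = max(int(math.floor(y - r)) - 1, 0)
        x1 = min(int(math.ceil(x + r)) + 2, w)
        y1 = min(int(math.ceil(y + r)) + 2, h)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - x) ** 2 + (yy - y) ** 2
        sigma = r / 2.0
        dome = np.exp(-d2 / (2.0 * sigma ** 2))
        dome[d2 > r * r] = 0.0
        delta = dome[..., None] * (np.asarray(col, dtype=float) - agar)
        patch = canvas[y0:y1, x0:x1]
        np.maximum(patch, delta, out=patch)


def _render_flat_discs(canvas: np.ndarray, xs, ys, radii_px, values):
    """Max-blend flat discs (hard edge) onto a float grayscale canvas."""
    h, w = canvas.shape
    for x, y, r, v in zip(xs, ys, radii_px, values):
        x0 = max(int(math.floor(x - r)) - 1, 0)
        y0 = max(int(math.floor(y - r)) - 1, 0)
        x1 = min(int(math.ceil(x + r)) + 2, w)
        y1 = min(int(math.ceil(y + r)) + 2, h)
        if x1 <= x0 or y1 <= y0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
        patch = canvas[y0:y1, x0:x1]
        np.maximum(patch, inside * float(v), out=patch)


def generate_plate(params: PlateParams) -> tuple[PlateImage, GroundTruthPlate]:
    """Render one synthetic plate and its exhaustive ground truth.

    Deterministic for a fixed ``params.seed`` (bit-identical images).
    Raises :class:`PlacementError` when the requested colonies cannot be
    placed within the retry budget.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_colonies
    scale = params.scale_mm_per_px
    cx, cy = params.center_px
    size = params.image_size_px

    radii_mm = _sample_radii(params, n, rng)
    xs, ys, gids = _place_colonies(params, radii_mm, rng)
    radii_px = radii_mm / scale

    phen_idx = _mix_choice(rng, params.color_phenotypes, n) if n else np.empty(0, int)
    colors = np.array([params.color_phenotypes[i][0] for i in phen_idx],
                      dtype=float).reshape(n, 3)
    if params.fluorescence_levels is not None and n:
        fl_idx = _mix_choice(rng, params.fluorescence_levels, n)
        fluor = np.array([params.fluorescence_levels[i][0] for i in fl_idx])
    else:
        fluor = np.full(n, np.nan)

    # Artifacts: small bright specks on the agar.
    na = params.artifact_count
    if na:
        a_r_mm = rng.uniform(0.15, 0.4, size=na)
        rad = np.sqrt(rng.uniform(0.0, (params.inner_radius_px * 0.92) ** 2, size=na))
        ang = rng.uniform(0.0, 2.0 * math.pi, size=na)
        a_x = cx + rad * np.cos(ang)
        a_y = cy + rad * np.sin(ang)
    else:
        a_r_mm = a_x = a_y = np.empty(0)

    # --- render RGB -----------------------------------------------------
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    d = np.hypot(xx - cx, yy - cy)
    ring_w = np.clip(params.outer_radius_px + 0.5 - d, 0.0, 1.0)
    inner_w = np.clip(params.inner_radius_px + 0.5 - d, 0.0, 1.0)
    base = (_BG_COLOR
            + (_WALL_COLOR - _BG_COLOR) * ring_w[..., None]
            + (_AGAR_COLOR - _WALL_COLOR) * inner_w[..., None])

    domes = np.zeros((size, size, 3))
    _render_domes(domes, xs, ys, radii_px, colors, _AGAR_COLOR)
    if na:
        _render_domes(domes, a_x, a_y, a_r_mm / scale,
                      [_ARTIFACT_COLOR] * na, _AGAR_COLOR)
    img = base + domes * inner_w[..., None]

    if params.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        u = ((xx - size / 2) * math.cos(theta)
             + (yy - size / 2) * math.sin(theta)) / (size / 2)
        img = img * (1.0 + params.illumination_gradient * u[..., None] / math.sqrt(2))

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)

    # --- render fluorescence -------------------------------------------
    fluor_img = None
    if params.fluorescence_levels is not None:
        fc = np.full((size, size), _FLUOR_BG)
        if n:
            _render_flat_discs(fc, xs, ys, radii_px, fluor)
        if params.noise_sigma > 0:
            fc = fc + rng.normal(0.0, params.noise_sigma, size=fc.shape)
        fluor_img = np.clip(fc, 0, 255).astype(np.uint8)

    # --- ground truth ---------------------------------------------------
    dist_mm = np.hypot(xs - cx, ys - cy) * scale if n else np.empty(0)
    pickable = ((dist_mm <= params.inner_radius_mm - params.margin_mm)
                & (2 * radii_mm >= params.min_pick_diameter_mm)) if n else np.empty(0, bool)
    colonies = pd.DataFrame({
        "id": np.arange(n, dtype=int),
        "x_px": xs, "y_px": ys,
        "x_mm": (xs - cx) * scale, "y_mm": (ys - cy) * scale,
        "radius_mm": radii_mm,
        "phenotype": phen_idx.astype(int) if n else np.empty(0, int),
        "color_r": colors[:, 0] if n else np.empty(0),
        "color_g": colors[:, 1] if n else np.empty(0),
        "color_b": colors[:, 2] if n else np.empty(0),
        "fluorescence": fluor,
        "group_id": gids,
        "pickable": pickable.astype(bool),
    }, columns=_COLONY_COLS)
    artifacts = pd.DataFrame({
        "id": np.arange(na, dtype=int),
        "x_px": a_x, "y_px": a_y,
        "radius_mm": a_r_mm,
    }, columns=_ARTIFACT_COLS)

    dish = DishTruth((cx, cy), params.outer_radius_px, params.inner_radius_px)
    gt = GroundTruthPlate(colonies, artifacts, dish, params)
    return PlateImage(rgb, fluor_img, scale), gt


@dataclass(frozen=True)
class BenchmarkParams:
    """A reproducible multi-plate benchmark profile."""

    name: str = "benchmark-v1"
    n_plates: int = 20
    master_seed: int = 42
    n_colonies_range: tuple[int, int] = (12, 453)
    group_fraction: float = 0.10
    border_fraction: float = 0.05
    artifact_count: int = 3
    illumination_gradient: float = 0.10
    noise_sigma: float = 3.0
    colony_radius_range_mm: tuple[float, float] = (0.6, 2.5)
    scale_mm_per_px: float = 0.1
    image_size_px: int = 1000
    dish_outer_diameter_range_mm: tuple[float, float] = (85.0, 89.0)


def benchmark_v1() -> BenchmarkParams:
    """The canonical fixed benchmark profile (20 plates, master seed 42)."""
    return BenchmarkParams()


def generate_benchmark(benchmark: BenchmarkParams | None = None):
    """Generate the plates of a benchmark profile.

    Returns a list of (PlateImage, GroundTruthPlate).  Per-plate colony
    counts are drawn uniformly from ``n_colonies_range`` (inclusive); dish
    diameter and a small centre jitter vary per plate.
    """
    b = benchmark or benchmark_v1()
    rng = np.random.default_rng(b.master_seed)
    plates = []
    for _ in range(b.n_plates):
        seed = int(rng.integers(0, 2**31 - 1))
        n = int(rng.integers(b.n_colonies_range[0], b.n_colonies_range[1] + 1))
        diam = float(rng.uniform(*b.dish_outer_diameter_range_mm))
        jitter = rng.uniform(-30.0, 30.0, size=2)
        c = b.image_size_px / 2.0
        params = PlateParams(
            image_size_px=b.image_size_px,
            dish_outer_diameter_mm=diam,
            dish_center_px=(c + jitter[0], c + jitter[1]),
            scale_mm_per_px=b.scale_mm_per_px,
            n_colonies=n,
            group_fraction=b.group_fraction,
            border_fraction=b.border_fraction,
            artifact_count=b.artifact_count,
            illumination_gradient=b.illumination_gradient,
            noise_sigma=b.noise_sigma,
            colony_radius_range_mm=b.colony_radius_range_mm,
            seed=seed,
        )
        plates.append(generate_plate(params))
    return plates


def write_ground_truth(gt: GroundTruthPlate, path) -> None:
    """Write ground truth to CSV (one row per colony/artifact).

    Dish geometry and the generating parameters are echoed in ``#``-prefixed
    header comment lines as JSON; :func:`read_ground_truth` restores them.
    """
    meta = {
        "dish": {"center_px": list(gt.dish.center_px),
                 "outer_radius_px": gt.dish.outer_radius_px,
                 "inner_radius_px": gt.dish.inner_radius_px},
        "params": asdict(gt.params),
    }
    col = gt.colonies.copy()
    col.insert(0, "record_type", "colony")
    art = gt.artifacts.copy()
    art.insert(0, "record_type", "artifact")
    rows = pd.concat([col, art], ignore_index=True)
    buf = io.StringIO()
    buf.write("# platepick ground truth v1\n")
    buf.write("# " + json.dumps(meta) + "\n")
    rows.to_csv(buf, index=False)
    try:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write ground truth to {path}: {exc}") from exc


def read_ground_truth(path) -> GroundTruthPlate:
    """Read a ground-truth CSV written by :func:`write_ground_truth`."""
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise OSError(f"cannot read ground truth from {path}: {exc}") from exc
    meta_line = next(ln for ln in lines if ln.startswith("# {"))
    meta = json.loads(meta_line[2:])
    body = "".join(ln for ln in lines if not ln.startswith("#"))
    rows = pd.read_csv(io.StringIO(body))
    col = rows[rows["record_type"] == "colony"].drop(columns="record_type")
    art = rows[rows["record_type"] == "artifact"].drop(columns="record_type")
    colonies = col.reindex(columns=_COLONY_COLS).reset_index(drop=True)
    if len(colonies):
        colonies = colonies.astype({"id": int, "phenotype": int,
                                    "group_id": int, "pickable": bool})
    else:
        colonies = colonies.astype({c: t for c, t in
                                    [("id", int), ("phenotype", int),
                                     ("group_id", int), ("pickable", bool)]})
    artifacts = art.reindex(columns=_ARTIFACT_COLS).reset_index(drop=True)
    if len(artifacts):
        artifacts = artifacts.astype({"id": int})
    else:
        artifacts = artifacts.astype({"id": int})
    p = dict(meta["params"])
    for key in ("dish_center_px", "colony_radius_range_mm"):
        if p.get(key) is not None:
            p[key] = tuple(p[key])
    p["color_phenotypes"] = tuple((tuple(c), f) for c, f in p["color_phenotypes"])
    if p.get("fluorescence_levels") is not None:
        p["fluorescence_levels"] = tuple((lv, f) for lv, f in p["fluorescence_levels"])
    params = PlateParams(**p)
    d = meta["dish"]
    dish = DishTruth(tuple(d["center_px"]), d["outer_radius_px"],
                     d["inner_radius_px"])
    return GroundTruthPlate(colonies, artifacts, dish, params)
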