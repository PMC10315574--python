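"""Multicriteria colony screening: filter, score, rank, assign wells.

Each candidate colony receives three marks in [0, 1] — size (min-max
normalized area over the candidate set), color (similarity or
dissimilarity to a target color in an HSV cone embedding) and
fluorescence (mean intensity / 255) — combined into a normalized unitary
score by a user-weighted sum.  Selection takes the top-k by descending
score and assigns destination wells column-wise (A1, B1, ..., H1, A2, ...).
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field

import numpy as np

from .colonies import ColonyFootprint

__all__ = [
    "HsvBox",
    "ScreeningCriteria",
    "ColonyScore",
    "WellLayout",
    "color_filter",
    "score_colonies",
    "rank_and_select",
    "assign_destinations",
    "hsv_cone_distance",
]


@dataclass(frozen=True)
class HsvBox:
    """An inclusive HSV box; the hue interval may wrap through 360."""

    h_min: float = 0.0
    h_max: float = 360.0
    s_min: float = 0.0
    s_max: float = 1.0
    v_min: float = 0.0
    v_max: float = 1.0

    def contains(self, hsv: tuple[float, float, float]) -> bool:
        h, s, v = hsv
        h %= 360.0
        if self.h_min <= self.h_max:
            h_ok = self.h_min <= h <= self.h_max
        else:                       # wrapping interval, e.g. 330..30
            h_ok = h >= self.h_min or h <= self.h_max
        return h_ok and self.s_min <= s <= self.s_max \
            and self.v_min <= v <= self.v_max


@dataclass(frozen=True)
class ScreeningCriteria:
    """User screening configuration.

    ``weights`` = (w_size, w_color, w_fluor), non-negative; normalized to
    sum to 1 on construction.  ``target_color`` is RGB (0-255), converted
    to HSV internally.  ``color_mode`` selects whether similarity or
    dissimilarity to the target scores high.
    """

    weights: tuple[float, float, float] = (1.0, 0.0, 0.0)
    target_color: tuple[int, int, int] = (255, 255, 255)
    color_mode: str = "similar"             # "similar" | "dissimilar"
    color_range: HsvBox | None = None
    color_range_mode: str = "select"        # "select" | "exclude"
    size_range_mm: tuple[float, float] | None = None
    k: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with a positive sum")
        object.__setattr__(self, "weights", tuple(w / w.sum()))
        if self.color_mode not in ("similar", "dissimilar"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        if self.color_range_mode not in ("select", "exclude"):
            raise ValueError(f"unknown color_range_mode {self.color_range_mode!r}")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    @property
    def target_hsv(self) -> tuple[float, float, float]:
        r, g, b = (c / 255.0 for c in self.target_color)
        h, s, v = colorsys.rgb_to_hsv(r, g, b)
        return (h * 360.0, s, v)


@dataclass
class ColonyScore:
    """Per-colony marks and the weighted total, all in [0, 1]."""

    colony_id: int
    m_size: float
    m_color: float
    m_fluor: float
    total: float


@dataclass(frozen=True)
class WellLayout:
    """Destination multiwell plate layout (default 96-well, 8 x 12)."""

    rows: int = 8
    cols: int = 12

    def well_name(self, index: int) -> str:
        if not 0 <= index < self.rows * self.cols:
            raise ValueError(f"well index {index} outside {self.rows}x{self.cols}")
        return f"{chr(ord('A') + index % self.rows)}{index // self.rows + 1}"


def hsv_cone_distance(a: tuple[float, float, float],
                      b: tuple[float, float, float]) -> float:
    """Euclidean distance in the HSV cone embedding (S cosH, S sinH, V).

    Handles the hue wrap and makes desaturated colors hue-agnostic.
    """
    def embed(hsv):
        h, s, v = hsv
        ang = math.radians(h)
        return (s * math.cos(ang), s * math.sin(ang), v)
    xa, ya, za = embed(a)
    xb, yb, zb = embed(b)
    return math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)


def color_filter(fps: list[ColonyFootprint], color_range: HsvBox,
                 mode: str = "select") -> list[ColonyFootprint]:
    """Keep colonies whose mean HSV lies inside (select) / outside
    (exclude) the box."""
    if mode not in ("select", "exclude"):
        raise ValueError(f"unknown color filter mode {mode!r}")
    keep_inside = mode == "select"
    out = []
    for fp in fps:
        if fp.mean_hsv is None:
            raise ValueError(f"footprint {fp.id} has no measured color")
        if color_range.contains(fp.mean_hsv) == keep_inside:
            out.append(fp)
    return out


def score_colonies(fps: list[ColonyFootprint],
                   criteria: ScreeningCriteria) -> list[ColonyScore]:
    """Score candidates by the weighted sum of size/color/fluorescence marks.

    Size is min-max normalized over the candidate set (degenerate spread
    scores 1); color is 1 - d/d_max in similar mode, d/d_max in dissimilar
    mode, with d the HSV cone distance to the target; fluorescence is the
    mean intensity on the unit scale.
    """
    if not fps:
        raise ValueError("no candidate colonies to score")
    w_size, w_color, w_fluor = criteria.weights

    areas = np.array([fp.area_px for fp in fps], dtype=float)
    lo, hi = areas.min(), areas.max()
    m_size = np.ones_like(areas) if hi == lo else (areas - lo) / (hi - lo)

    target = criteria.target_hsv
    dists = np.empty(len(fps))
    for i, fp in enumerate(fps):
        if fp.mean_hsv is None:
            raise ValueError(f"footprint {fp.id} has no measured color")
        dists[i] = hsv_cone_distance(fp.mean_hsv, target)
    d_max = dists.max()
    rel = np.zeros_like(dists) if d_max == 0 else dists / d_max
    m_color = rel if criteria.color_mode == "dissimilar" else 1.0 - rel

    m_fluor = np.zeros(len(fps))
    if w_fluor > 0:
        for i, fp in enumerate(fps):
            if fp.mean_fluorescence is None:
                raise ValueError(
                    f"fluorescence weighted but footprint {fp.id} has no "
                    "fluorescence measurement")
            m_fluor[i] = fp.mean_fluorescence / 255.0

    return [ColonyScore(fp.id, float(m_size[i]), float(m_color[i]),
                        float(m_fluor[i]),
                        float(w_size * m_size[i] + w_color * m_color[i]
                              + w_fluor * m_fluor[i]))
            for i, fp in enumerate(fps)]


def rank_and_select(scores: list[ColonyScore], k: int) -> list[int]:
    """Ids of the top-k colonies by descending score (ties by ascending id)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(scores, key=lambda s: (-s.total, s.colony_id))
    return [s.colony_id for s in ordered[:min(k, len(ordered))]]


def assign_destinations(selection: list[int],
                        dest_layout: WellLayout | None = None
                        ) -> list[tuple[int, str]]:
    """Assign destination wells column-wise in selection order."""
    layout = dest_layout or WellLayout()
    if len(selection) > layout.rows * layout.cols:
        raise ValueError(
            f"{len(selection)} picks overflow the {layout.rows}x{layout.cols} "
            "destination layout")
    return [(cid, layout.well_name(i)) for i, cid in enumerate(selection)]
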