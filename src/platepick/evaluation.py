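"""Detection evaluation: match detections to ground truth, compute metrics.

Detections are matched to ground-truth colonies by greedy
nearest-neighbour pairing within a millimetre tolerance (default 1 mm,
the robotic picking tolerance).  Ground-truth colonies inside the wall
security margin are "not pickable" and excluded from the pickable
metrics; surplus detections become false positives, with detections on
known specks tallied separately as detected artifacts.  Metrics follow
the detection convention (no true negatives): sensitivity TP/(TP+FN),
precision TP/(TP+FP), accuracy TP/(TP+FP+FN) — a Jaccard-style index —
plus raw performance (matched fraction) over all and over pickable
colonies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .colonies import ColonyFootprint
from .synthetic import GroundTruthPlate

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_detections",
    "compute_metrics",
    "aggregate_matches",
]


@dataclass
class MatchResult:
    """Matched/unmatched counts and the event taxonomy for one plate."""

    TP: int = 0                 # matched pickable truths
    FP: int = 0                 # detections matching no truth
    FN: int = 0                 # unmatched pickable truths
    detected: int = 0           # detections matched to any truth
    picked: int = 0             # detections actually selected for picking
    detected_artifacts: int = 0  # FP detections on known specks
    not_pickable: int = 0       # truths inside the security margin
    not_detected: int = 0       # alias of FN in the event taxonomy
    multi_pick: int = 0         # one truth hit by >= 2 detections
    group_as_single: int = 0    # one detection covering >= 2 truth centres
    total_truths: int = 0
    pickable_truths: int = 0

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(**{k: getattr(self, k) + getattr(other, k)
                              for k in self.__dataclass_fields__})


@dataclass
class EvalReport:
    """Benchmark metrics as fractions in [0, 1] (None when undefined)."""

    raw_performance_all: float | None
    raw_performance_pickable: float | None
    accuracy: float | None
    misclassification_rate: float | None
    sensitivity: float | None
    precision: float | None

    def to_json(self, path=None) -> str:
        text = json.dumps({k: v for k, v in asdict(self).items()}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> str:
        rows = []
        for k, v in asdict(self).items():
            val = "undefined" if v is None else f"{100 * v:6.1f} %"
            rows.append(f"{k:<28s} {val}")
        return "\n".join(rows)


def match_detections(fps: list[ColonyFootprint], gt: GroundTruthPlate,
                     dish_center_local: tuple[float, float],
                     scale_mm_per_px: float,
                     tol_mm: float = 1.0) -> MatchResult:
    """Greedy nearest-neighbour matching of detections to ground truth.

    Detection centroids (crop-local px, relative to the detected dish
    centre ``dish_center_local``) and ground-truth centres (mm relative
    to the true dish centre) are compared in the common dish-centred mm
    frame.  Candidate pairs within ``tol_mm`` are matched closest-first,
    one-to-one.
    """
    if tol_mm <= 0:
        raise ValueError("tol_mm must be > 0")
    n_det = len(fps)
    det_mm = np.array([[(fp.centroid[0] - dish_center_local[0]) * scale_mm_per_px,
                        (fp.centroid[1] - dish_center_local[1]) * scale_mm_per_px]
                       for fp in fps]).reshape(n_det, 2)
    truths = gt.colonies
    n_tru = len(truths)
    tru_mm = truths[["x_mm", "y_mm"]].to_numpy().reshape(n_tru, 2)
    pickable = truths["pickable"].to_numpy(dtype=bool) if n_tru else np.empty(0, bool)

    res = MatchResult(total_truths=n_tru,
                      pickable_truths=int(pickable.sum()),
                      not_pickable=int((~pickable).sum()))
    if n_det and n_tru:
        diff = det_mm[:, None, :] - tru_mm[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        pairs = np.argwhere(dist <= tol_mm)
        order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
        det_match = np.full(n_det, -1)
        tru_match = np.full(n_tru, -1)
        for di, ti in pairs[order]:
            if det_match[di] == -1 and tru_match[ti] == -1:
                det_match[di] = ti
                tru_match[ti] = di
    else:
        det_match = np.full(n_det, -1)
        tru_match = np.full(n_tru, -1)
        dist = np.zeros((n_det, n_tru))

    res.detected = int((det_match >= 0).sum())
    matched_truths = tru_match >= 0
    res.TP = int((matched_truths & pickable).sum())
    res.FN = int((~matched_truths & pickable).sum())
    res.not_detected = res.FN

    # Surplus detections: artifacts, multi-picks, plain false positives.
    art = gt.artifacts
    art_mm = (np.column_stack([
        (art["x_px"].to_numpy() - gt.dish.center_px[0]),
        (art["y_px"].to_numpy() - gt.dish.center_px[1]),
    ]) * gt.params.scale_mm_per_px) if len(art) else np.empty((0, 2))
    for di in range(n_det):
        if det_match[di] >= 0:
            continue
        res.FP += 1
        if len(art_mm):
            d_art = np.hypot(art_mm[:, 0] - det_mm[di, 0],
                             art_mm[:, 1] - det_mm[di, 1])
            if d_art.min() <= tol_mm:
                res.detected_artifacts += 1
                continue
        if n_tru:
            d_tru = dist[di]
            ti = int(np.argmin(d_tru))
            if d_tru[ti] <= tol_mm and tru_match[ti] != -1:
                res.multi_pick += 1

    # One detection mask covering >= 2 truth centres.
    if n_tru:
        tru_px = np.column_stack([
            tru_mm[:, 0] / scale_mm_per_px + dish_center_local[0],
            tru_mm[:, 1] / scale_mm_per_px + dish_center_local[1]])
        for fp in fps:
            covered = sum(1 for x, y in tru_px if fp.contains(x, y))
            if covered >= 2:
                res.group_as_single += 1
    return res


def aggregate_matches(results: list[MatchResult]) -> MatchResult:
    """Pool per-plate match counts (metrics on the pool equal metrics on
    summed counts)."""
    total = MatchResult()
    for r in results:
        total = total + r
    return total


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(m: MatchResult) -> EvalReport:
    """Compute the benchmark metrics from pooled match counts."""
    acc = _ratio(m.TP, m.TP + m.FP + m.FN)
    return EvalReport(
        raw_performance_all=_ratio(m.detected, m.total_truths),
        raw_performance_pickable=_ratio(m.TP, m.pickable_truths),
        accuracy=acc,
        misclassification_rate=None if acc is None else 1.0 - acc,
        sensitivity=_ratio(m.TP, m.TP + m.FN),
        precision=_ratio(m.TP, m.TP + m.FP),
    )
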