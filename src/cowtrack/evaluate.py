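"""Evaluation metrics: landmark error, Fréchet distance, artery tracking
correctness, and F1 of the path classifier.

Centerline similarity uses the discrete Fréchet distance on polylines
resampled to equidistant points (default 0.25 mm step): the minimum over
monotone couplings of the maximum pointwise distance.  The qualitative
"correct artery tracked" judgement is operationalized as at least 95% of
path nodes lying within the ground-truth tube dilated by a tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.metrics import precision_recall_fscore_support

from .classify import LABEL_HYPO_APLASTIC, LABEL_NORMAL
from .landmarks import LandmarkSet
from .phantom import APLASTIC, GroundTruthGraph
from .tracking import ArteryPath


class NotEvaluableError(ValueError):
    """A metric is undefined for this input (e.g. an aplastic segment)."""


def landmark_error(predicted: LandmarkSet, truth: LandmarkSet) -> dict[str, float]:
    """Per-name Euclidean distance (mm) between predicted and true points."""
    if set(predicted.points) != set(truth.points):
        raise ValueError("landmark name sets differ")
    return {
        name: float(np.linalg.norm(predicted.points[name] - truth.points[name]))
        for name in sorted(predicted.points)
    }


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to equidistant points at most ``step`` mm apart."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("polyline must have at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate zero-length polyline")
    n = max(2, int(np.ceil(s[-1] / step)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def discrete_frechet(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences (no resampling)."""
    d = cdist(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    n, m = d.shape
    f = np.empty_like(d)
    f[0, 0] = d[0, 0]
    for j in range(1, m):
        f[0, j] = max(f[0, j - 1], d[0, j])
    for i in range(1, n):
        f[i, 0] = max(f[i - 1, 0], d[i, 0])
        for j in range(1, m):
            f[i, j] = max(min(f[i - 1, j], f[i - 1, j - 1], f[i, j - 1]), d[i, j])
    return float(f[-1, -1])


def frechet(path_a, path_b, resample_step: float = 0.25) -> float:
    """Discrete Fréchet distance after equidistant resampling (mm)."""
    a = path_a.points if isinstance(path_a, ArteryPath) else np.asarray(path_a, dtype=float)
    b = path_b.points if isinstance(path_b, ArteryPath) else np.asarray(path_b, dtype=float)
    return discrete_frechet(resample_polyline(a, resample_step), resample_polyline(b, resample_step))


def correct_artery(
    path: ArteryPath,
    gt: GroundTruthGraph,
    segment_label: str,
    tolerance_mm: float = 0.5,
    min_inside_fraction: float = 0.95,
) -> bool:
    """Whether the path stays inside the segment's dilated ground-truth tube.

    Aplastic segments have no reference trajectory and raise
    :class:`NotEvaluableError`.
    """
    seg = gt.edges[segment_label]
    if seg.status == APLASTIC:
        raise NotEvaluableError(f"segment {segment_label} is aplastic: no reference path")
    dense = resample_polyline(seg.centerline, 0.1)
    dist, _ = cKDTree(dense).query(path.points)
    inside = dist <= seg.radius + tolerance_mm
    return bool(inside.mean() >= min_inside_fraction)


def f1(labels_pred: list[str], labels_true: list[str]) -> dict[str, float]:
    """Precision/recall/F1 with hypo-/aplastic positive, plus macro F1."""
    if len(labels_pred) == 0 or len(labels_pred) != len(labels_true):
        raise ValueError("need equal-length, non-empty label lists")
    order = [LABEL_NORMAL, LABEL_HYPO_APLASTIC]
    p, r, f, _ = precision_recall_fscore_support(
        labels_true, labels_pred, labels=order, zero_division=0
    )
    return {
        "precision": float(p[1]),
        "recall": float(r[1]),
        "f1": float(f[1]),
        "f1_normal": float(f[0]),
        "macro_f1": float((f[0] + f[1]) / 2.0),
    }


@dataclass
class EvalReport:
    """Aggregated per-case metrics; serializable as JSON and flat CSV."""

    landmark_errors_mm: dict[str, float] = field(default_factory=dict)
    frechet_mm: dict[str, float] = field(default_factory=dict)
    correct: dict[str, bool] = field(default_factory=dict)
    classification: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        out = {}
        if self.landmark_errors_mm:
            e = np.array(list(self.landmark_errors_mm.values()))
            out["median_landmark_error_mm"] = float(np.median(e))
        if self.frechet_mm:
            d = np.array(list(self.frechet_mm.values()))
            out["median_frechet_mm"] = float(np.median(d))
            out["iqr_frechet_mm"] = float(np.percentile(d, 75) - np.percentile(d, 25))
        if self.correct:
            out["correct_artery_rate"] = float(np.mean(list(self.correct.values())))
        out.update(self.classification)
        return out

    def to_json(self, path) -> None:
        obj = {
            "landmark_errors_mm": self.landmark_errors_mm,
            "frechet_mm": self.frechet_mm,
            "correct_artery": self.correct,
            "classification": self.classification,
            "summary": self.summary(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1)

    def to_csv(self, path) -> None:
        rows = ["metric,name,value"]
        for name, v in sorted(self.landmark_errors_mm.items()):
            rows.append(f"landmark_error_mm,{name},{v:.6f}")
        for name, v in sorted(self.frechet_mm.items()):
            rows.append(f"frechet_mm,{name},{v:.6f}")
        for name, v in sorted(self.correct.items()):
            rows.append(f"correct_artery,{name},{int(v)}")
        for name, v in sorted(self.classification.items()):
            rows.append(f"classification,{name},{v:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
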