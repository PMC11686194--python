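"""Artery path classification and labelled CoW graph reconstruction.

Each extracted path is summarized by 50 intensity samples at equidistant
arc-length positions along it (in the [0,1]-normalized volume) and
classified normal vs hypo-/aplastic — hypoplasia meaning a diameter below
1 mm, with no distinction between hypo- and aplasia — by a Random Forest
of 100 depth-2 trees with balanced class weights.  The classified edges
plus the nine bifurcation nodes form the output graph, whose anterior and
posterior sections are assigned Lippert classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import networkx as nx
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .landmarks import LandmarkSet
from .phantom import NORMAL, GroundTruthGraph
from .template import ANTERIOR_SEGMENTS, COW_EDGES, POSTERIOR_SEGMENTS, SEGMENT_LABELS
from .tracking import ArteryPath
from .volume import Volume

N_PROFILE_SAMPLES = 50
LABEL_NORMAL = "normal"
LABEL_HYPO_APLASTIC = "hypo-aplastic"


@dataclass
class IntensityProfile:
    """50 normalized intensity samples along one path, ordered seed→sink."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != N_PROFILE_SAMPLES:
            raise ValueError(f"profile must have exactly {N_PROFILE_SAMPLES} samples")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("profile values must lie in [0, 1] (normalized volume)")


@dataclass
class PathLabel:
    """Binary path label with the hypo-/aplastic vote fraction as score."""

    label: str
    score: float
    threshold: float = 0.5

    def __post_init__(self) -> None:
        expected = LABEL_HYPO_APLASTIC if self.score >= self.threshold else LABEL_NORMAL
        if self.label != expected:
            raise ValueError("label inconsistent with score and threshold")


def profile(path_or_points, volume_normalized: Volume, label: str = "") -> IntensityProfile:
    """Resample a path to 50 equidistant arc-length positions and sample I.

    Accepts an :class:`ArteryPath` or an (n, 3) polyline.  The profile is
    order-sensitive: reversing the path reverses the profile.
    """
    if isinstance(path_or_points, ArteryPath):
        pts = path_or_points.points
        label = label or path_or_points.label
    else:
        pts = np.asarray(path_or_points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("path must have at least 2 nodes")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("degenerate zero-length path")
    si = np.linspace(0.0, s[-1], N_PROFILE_SAMPLES)
    samples = np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])
    values = np.clip(volume_normalized.sample(samples), 0.0, 1.0)
    return IntensityProfile(label=label, values=values)


# ---------------------------------------------------------------------------
# Random Forest


def train_rf(
    profiles: list[IntensityProfile],
    labels: list[str],
    n_trees: int = 100,
    max_depth: int = 2,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the binary path classifier on 50-feature intensity profiles."""
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must have equal length")
    classes = set(labels)
    if classes - {LABEL_NORMAL, LABEL_HYPO_APLASTIC}:
        raise ValueError(f"unknown labels {classes - {LABEL_NORMAL, LABEL_HYPO_APLASTIC}}")
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    X = np.stack([p.values for p in profiles])
    y = np.asarray([1 if l == LABEL_HYPO_APLASTIC else 0 for l in labels])
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        class_weight="balanced",
        random_state=seed,
    )
    model.fit(X, y)
    return model


def classify_paths(
    model: RandomForestClassifier,
    profiles: list[IntensityProfile],
    threshold: float = 0.5,
) -> list[PathLabel]:
    """Vote-fraction classification of each profile, in input order.

    The score is the hypo-/aplastic vote fraction; score >= threshold
    labels the path hypo-/aplastic.
    """
    X = np.stack([p.values for p in profiles])
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"profiles have {X.shape[1]} features, model expects {model.n_features_in_}"
        )
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    scores = model.predict_proba(X)[:, pos_col]
    return [
        PathLabel(
            label=LABEL_HYPO_APLASTIC if s >= threshold else LABEL_NORMAL,
            score=float(s),
            threshold=threshold,
        )
        for s in scores
    ]


def save_model(model: RandomForestClassifier, path, config: dict | None = None) -> None:
    joblib.dump({"model": model, "config": config or {}}, str(path))


def load_model(path) -> RandomForestClassifier:
    return joblib.load(str(path))["model"]


def training_profiles_from_ground_truth(
    volume_normalized: Volume, gt: GroundTruthGraph
) -> tuple[list[IntensityProfile], list[str]]:
    """Training exemplars sampled along ground-truth centerlines.

    Aplastic segments contribute the straight corridor between their two
    bifurcations (matching what a forced reconstruction traverses).
    """
    profiles, labels = [], []
    for seg_label in SEGMENT_LABELS:
        seg = gt.edges[seg_label]
        line = gt.nominal_centerline(seg_label)
        profiles.append(profile(line, volume_normalized, label=seg_label))
        labels.append(LABEL_NORMAL if seg.status == NORMAL else LABEL_HYPO_APLASTIC)
    return profiles, labels


# ---------------------------------------------------------------------------
# Lippert classification


@dataclass
class LippertMapping:
    """Configurable mapping from segment label patterns to Lippert classes.

    Defaults (anterior over {ACA-A1-L, ACA-A1-R, AcoA}; posterior over
    {PCA-P1-L, PCA-P1-R, PcoA-L, PcoA-R}; "h/a" = hypo-/aplastic):

    * anterior: A = all normal; B = AcoA h/a only; C = any A1 h/a.
    * posterior: P0 = all normal; P1 = one PcoA h/a; P2 = both PcoAs h/a;
      P3 = any P1 h/a with both PcoAs normal; P4 = P1 and PcoA h/a.

    ``overrides`` maps explicit patterns (tuples of booleans, True =
    hypo-/aplastic, in template segment order of the section) to class
    ids; patterns not covered by rules or overrides map to "other".
    """

    anterior_overrides: dict[tuple[bool, ...], str] = field(default_factory=dict)
    posterior_overrides: dict[tuple[bool, ...], str] = field(default_factory=dict)

    def anterior(self, ha: dict[str, bool]) -> str:
        pattern = tuple(ha[s] for s in ANTERIOR_SEGMENTS)
        if pattern in self.anterior_overrides:
            return self.anterior_overrides[pattern]
        if ha["ACA-A1-L"] or ha["ACA-A1-R"]:
            return "C"
        if ha["AcoA"]:
            return "B"
        return "A"

    def posterior(self, ha: dict[str, bool]) -> str:
        pattern = tuple(ha[s] for s in POSTERIOR_SEGMENTS)
        if pattern in self.posterior_overrides:
            return self.posterior_overrides[pattern]
        any_p1 = ha["PCA-P1-L"] or ha["PCA-P1-R"]
        n_pcoa = int(ha["PcoA-L"]) + int(ha["PcoA-R"])
        if any_p1:
            return "P4" if n_pcoa > 0 else "P3"
        if n_pcoa == 2:
            return "P2"
        if n_pcoa == 1:
            return "P1"
        return "P0"


def lippert(
    edge_labels: dict[str, str], mapping: LippertMapping | None = None
) -> tuple[str, str]:
    """Anterior and posterior Lippert classes from the 7 segment labels."""
    missing = set(SEGMENT_LABELS) - set(edge_labels)
    if missing:
        raise ValueError(f"missing segment labels: {sorted(missing)}")
    mapping = mapping or LippertMapping()
    ha = {s: edge_labels[s] == LABEL_HYPO_APLASTIC for s in SEGMENT_LABELS}
    return mapping.anterior(ha), mapping.posterior(ha)


# ---------------------------------------------------------------------------
# output graph


@dataclass
class CowGraph:
    """The labelled CoW: 9 positioned nodes, 7 classified segment edges."""

    landmarks: LandmarkSet
    paths: dict[str, ArteryPath]
    labels: dict[str, PathLabel]
    anterior_class: str
    posterior_class: str

    @classmethod
    def build(
        cls,
        landmarks: LandmarkSet,
        paths: dict[str, ArteryPath],
        labels: dict[str, PathLabel],
        mapping: LippertMapping | None = None,
    ) -> "CowGraph":
        ant, post = lippert({k: v.label for k, v in labels.items()}, mapping)
        return cls(landmarks=landmarks, paths=paths, labels=labels,
                   anterior_class=ant, posterior_class=post)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(anterior_class=self.anterior_class, posterior_class=self.posterior_class)
        for name, pt in self.landmarks.points.items():
            g.add_node(name, x=float(pt[0]), y=float(pt[1]), z=float(pt[2]))
        for seg_label, (u, v) in COW_EDGES.items():
            lab = self.labels[seg_label]
            g.add_edge(
                u,
                v,
                segment=seg_label,
                label=lab.label,
                score=lab.score,
                length_mm=self.paths[seg_label].length_mm,
                n_nodes=len(self.paths[seg_label].points),
            )
        return g

    def to_json(self, path) -> None:
        obj = {
            "anterior_class": self.anterior_class,
            "posterior_class": self.posterior_class,
            "nodes": {k: [round(float(c), 6) for c in v] for k, v in self.landmarks.points.items()},
            "edges": {
                seg_label: {
                    "endpoints": list(COW_EDGES[seg_label]),
                    "label": self.labels[seg_label].label,
                    "score": round(self.labels[seg_label].score, 6),
                    "polyline_mm": [
                        [round(float(c), 6) for c in p] for p in self.paths[seg_label].points
                    ],
                    "total_cost": round(self.paths[seg_label].total_cost, 6),
                    "cost_kind": self.paths[seg_label].cost_kind,
                }
                for seg_label in SEGMENT_LABELS
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))
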