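"""Synthetic circle-of-Willis phantoms with exact ground truth.

Generates TOF-MRA-like volumes: bright tubular arteries on a dark noisy
background, seven CoW segments joining nine bifurcations, with diameters
spanning normal (>= 1.0 mm), hypoplastic (< 1.0 mm) and aplastic (absent)
segments.  The renderer thresholds a distance-to-centerline field at the
tube radius, applies Gaussian smoothing as a partial-volume surrogate, and
adds Gaussian noise — reproducing the key difficulty of the real imaging
problem (sub-voxel hypoplastic arteries fading into the background)
without a full MR physics model.

All operations are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .template import COW_EDGES, COW_NODE_NAMES, SEGMENT_LABELS
from .volume import Volume

NORMAL = "normal"
HYPOPLASTIC = "hypoplastic"
APLASTIC = "aplastic"

HYPOPLASIA_THRESHOLD_MM = 1.0

ANTERIOR_CLASSES = ("A", "B", "C")
POSTERIOR_CLASSES = ("P0", "P1", "P2", "P3", "P4")


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass
class SegmentSpec:
    """One CoW segment: centerline polyline (mm), diameter (mm), status."""

    label: str
    centerline: np.ndarray
    diameter: float
    status: str

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.status == APLASTIC:
            if len(self.centerline) != 0:
                raise ValueError(f"{self.label}: aplastic segment must have an empty centerline")
        else:
            if self.diameter <= 0:
                raise ValueError(f"{self.label}: diameter must be positive, got {self.diameter}")
            is_hypo = self.diameter < HYPOPLASIA_THRESHOLD_MM
            if is_hypo != (self.status == HYPOPLASTIC):
                raise ValueError(
                    f"{self.label}: status {self.status!r} inconsistent with "
                    f"diameter {self.diameter} mm (hypoplasia threshold "
                    f"{HYPOPLASIA_THRESHOLD_MM} mm)"
                )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Variant:
    """A drawn anatomical variant: class pair plus per-segment statuses."""

    anterior: str
    posterior: str
    statuses: dict[str, str]


@dataclass
class GroundTruthGraph:
    """Exact phantom ground truth: 9 nodes, 7 segments, variant classes.

    ``context_vessels`` are the distal continuations of the cerebral
    arteries beyond the circle (ICA trunks, M1, A2, P2, basilar): they are
    rendered and carry orientation signal like any artery, but are not CoW
    segments and have no labels — exactly the surrounding vasculature that
    intensity-guided tracking can leak into.
    """

    nodes: dict[str, np.ndarray]
    edges: dict[str, SegmentSpec]
    variant: tuple[str, str]
    context_vessels: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.nodes) != set(COW_NODE_NAMES):
            raise ValueError("ground-truth node set must match the CoW template")
        self.nodes = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.nodes.items()}

    def nominal_centerline(self, label: str, step: float = 0.25) -> np.ndarray:
        """The segment centerline; for aplastic segments, the straight
        corridor between its two template nodes (used for corridor queries,
        never as an anatomical ground truth)."""
        seg = self.edges[label]
        if seg.status != APLASTIC:
            return seg.centerline
        u, v = COW_EDGES[label]
        a, b = self.nodes[u], self.nodes[v]
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / step)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return a[None, :] * (1 - t) + b[None, :] * t

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "variant": {"anterior": self.variant[0], "posterior": self.variant[1]},
            "nodes": {k: list(v) for k, v in self.nodes.items()},
            "context_vessels": [
                {"centerline_mm": line.tolist(), "diameter_mm": d}
                for line, d in self.context_vessels
            ],
            "edges": {
                label: {
                    "status": seg.status,
                    "diameter_mm": seg.diameter,
                    "centerline_mm": seg.centerline.tolist(),
                }
                for label, seg in self.edges.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthGraph":
        with open(path) as fh:
            obj = json.load(fh)
        edges = {
            label: SegmentSpec(
                label=label,
                centerline=np.asarray(e["centerline_mm"], dtype=float).reshape(-1, 3),
                diameter=float(e["diameter_mm"]),
                status=e["status"],
            )
            for label, e in obj["edges"].items()
        }
        return cls(
            nodes={k: np.asarray(v) for k, v in obj["nodes"].items()},
            edges=edges,
            variant=(obj["variant"]["anterior"], obj["variant"]["posterior"]),
            context_vessels=[
                (np.asarray(c["centerline_mm"], dtype=float).reshape(-1, 3), float(c["diameter_mm"]))
                for c in obj.get("context_vessels", [])
            ],
        )

    def centerlines_to_csv(self, path) -> None:
        rows = ["label,x,y,z"]
        for label in SEGMENT_LABELS:
            for p in self.edges[label].centerline:
                rows.append(f"{label},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PrevalenceConfig:
    """Probability of each (anterior, posterior) Lippert class pair.

    The default is loosely population-like: complete anterior circles
    dominate, posterior variation is mostly one or two underdeveloped
    posterior communicating arteries.  ``hypo_fraction`` is the chance an
    underdeveloped segment is hypoplastic rather than aplastic.
    """

    probs: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("A", "P0"): 0.28,
            ("A", "P1"): 0.20,
            ("A", "P2"): 0.17,
            ("A", "P3"): 0.08,
            ("A", "P4"): 0.07,
            ("B", "P0"): 0.05,
            ("B", "P1"): 0.04,
            ("B", "P2"): 0.03,
            ("C", "P0"): 0.04,
            ("C", "P1"): 0.02,
            ("C", "P2"): 0.02,
        }
    )
    hypo_fraction: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class-pair probabilities must sum to 1, got {total}")
        for (a, p), w in self.probs.items():
            if a not in ANTERIOR_CLASSES or p not in POSTERIOR_CLASSES:
                raise ValueError(f"unknown class pair ({a}, {p})")
            if w < 0:
                raise ValueError("probabilities must be non-negative")


#: Nominal bifurcation layout (mm): x lateral, y anterior, z superior.
DEFAULT_NODE_POSITIONS: dict[str, tuple[float, float, float]] = {
    "ICA-T-L": (-9.0, 2.0, 0.0),
    "ICA-T-R": (9.0, 2.0, 0.0),
    "PcoA-ICA-L": (-8.7, 1.2, -2.0),
    "PcoA-ICA-R": (8.7, 1.2, -2.0),
    "A1A2-L": (-1.5, 10.0, 1.0),
    "A1A2-R": (1.5, 10.0, 1.0),
    "P1P2-L": (-7.0, -7.0, 0.0),
    "P1P2-R": (7.0, -7.0, 0.0),
    "BA-top": (0.0, -9.0, -1.0),
}

#: Mid-segment bow (mm) giving each artery a gentle, plausible curve.
DEFAULT_BOWS: dict[str, tuple[float, float, float]] = {
    "ACA-A1-L": (-1.5, 0.0, 0.8),
    "ACA-A1-R": (1.5, 0.0, 0.8),
    "AcoA": (0.0, 1.2, 0.4),
    "PCA-P1-L": (-1.0, -1.5, 0.5),
    "PCA-P1-R": (1.0, -1.5, 0.5),
    "PcoA-L": (-1.5, 0.0, 0.5),
    "PcoA-R": (1.5, 0.0, 0.5),
}

#: Per-segment normal diameter ranges (mm), matching typical CoW calibres.
DEFAULT_NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "ACA-A1-L": (1.6, 2.4),
    "ACA-A1-R": (1.6, 2.4),
    "AcoA": (1.0, 1.8),
    "PCA-P1-L": (1.5, 2.3),
    "PCA-P1-R": (1.5, 2.3),
    "PcoA-L": (1.0, 1.8),
    "PcoA-R": (1.0, 1.8),
}


#: Distal continuations rendered around the circle: (node, direction,
#: length mm, diameter mm).  Left-sided entries are mirrored in x for the
#: right side; the basilar trunk is midline.
DEFAULT_CONTEXT_STUBS: tuple[tuple[str, tuple[float, float, float], float, float], ...] = (
    ("ICA-T-L", (0.2, -0.7, -0.6), 8.0, 3.2),   # internal carotid trunk, via PcoA-ICA
    ("ICA-T-L", (-1.0, 0.1, 0.05), 8.0, 2.6),   # middle cerebral M1
    ("A1A2-L", (-0.1, 0.55, 0.83), 8.0, 2.0),   # anterior cerebral A2
    ("P1P2-L", (-0.85, -0.5, 0.15), 8.0, 2.1),  # posterior cerebral P2
    ("BA-top", (0.0, -0.1, -1.0), 8.0, 3.0),    # basilar trunk
)


@dataclass
class GeometryConfig:
    """Nominal node layout, curvature, and diameter ranges of the phantom."""

    node_positions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NODE_POSITIONS)
    )
    bows: dict[str, tuple[float, float, float]] = field(default_factory=lambda: dict(DEFAULT_BOWS))
    node_jitter_sd: float = 0.4
    bow_jitter_sd: float = 0.5
    sample_step: float = 0.2
    normal_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMAL_RANGES)
    )
    hypoplastic_range: tuple[float, float] = (0.5, 0.9)
    context_vessels: bool = True

    def __post_init__(self) -> None:
        if set(self.node_positions) != set(COW_NODE_NAMES):
            raise ValueError("node_positions must cover exactly the template nodes")
        lo, hi = self.hypoplastic_range
        if not (0.0 < lo <= hi < HYPOPLASIA_THRESHOLD_MM):
            raise ValueError(
                f"hypoplastic diameter range must lie inside (0, {HYPOPLASIA_THRESHOLD_MM}) mm"
            )
        for label, (a, b) in self.normal_ranges.items():
            if not (HYPOPLASIA_THRESHOLD_MM <= a <= b <= 3.0):
                raise ValueError(
                    f"normal diameter range for {label} must lie inside "
                    f"[{HYPOPLASIA_THRESHOLD_MM}, 3.0] mm, got ({a}, {b})"
                )
        if self.sample_step > 0.25:
            raise ValueError("centerline sample step must be <= 0.25 mm")


@dataclass
class NoiseSpec:
    """Rendering and noise parameters of the rasterizer."""

    background_mean: float = 20.0
    background_sd: float = 5.0
    lumen_peak: float = 100.0
    pv_sigma_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_peak <= self.background_mean:
            raise ValueError("lumen peak intensity must exceed the background mean")
        if self.background_sd < 0 or self.pv_sigma_mm < 0:
            raise ValueError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# operations


def sample_variant(prevalence: PrevalenceConfig, seed: int) -> Variant:
    """Draw an (anterior, posterior) class pair and resolve segment statuses."""
    rng = np.random.default_rng(seed)
    pairs = sorted(prevalence.probs)
    weights = np.array([prevalence.probs[p] for p in pairs])
    ant, post = pairs[rng.choice(len(pairs), p=weights / weights.sum())]

    def dev() -> str:
        return HYPOPLASTIC if rng.random() < prevalence.hypo_fraction else APLASTIC

    statuses = {label: NORMAL for label in SEGMENT_LABELS}
    if ant == "B":
        statuses["AcoA"] = dev()
    elif ant == "C":
        side = "L" if rng.random() < 0.5 else "R"
        statuses[f"ACA-A1-{side}"] = dev()
    if post == "P1":
        side = "L" if rng.random() < 0.5 else "R"
        statuses[f"PcoA-{side}"] = dev()
    elif post == "P2":
        statuses["PcoA-L"] = dev()
        statuses["PcoA-R"] = dev()
    elif post == "P3":
        side = "L" if rng.random() < 0.5 else "R"
        statuses[f"PCA-P1-{side}"] = dev()
    elif post == "P4":
        side = "L" if rng.random() < 0.5 else "R"
        statuses[f"PCA-P1-{side}"] = dev()
        statuses[f"PcoA-{side}"] = dev()
    return Variant(anterior=ant, posterior=post, statuses=statuses)


def _bezier(u: np.ndarray, c: np.ndarray, v: np.ndarray, step: float) -> np.ndarray:
    """Quadratic Bezier from u to v with control c, arc-length sampled <= step apart."""
    t = np.linspace(0.0, 1.0, 256)[:, None]
    fine = (1 - t) ** 2 * u + 2 * t * (1 - t) * c + t**2 * v
    pts = _resample_dense(fine, step)
    pts[0], pts[-1] = u, v  # endpoints exact
    return pts


def build_geometry(variant: Variant, config: GeometryConfig, seed: int) -> GroundTruthGraph:
    """Realize a variant as smooth centerlines and drawn diameters."""
    rng = np.random.default_rng(seed)
    nodes = {
        name: np.asarray(config.node_positions[name], dtype=float)
        + rng.normal(0.0, config.node_jitter_sd, 3)
        for name in COW_NODE_NAMES
    }
    edges: dict[str, SegmentSpec] = {}
    for label in SEGMENT_LABELS:
        status = variant.statuses[label]
        if status == APLASTIC:
            edges[label] = SegmentSpec(label, np.empty((0, 3)), 0.0, APLASTIC)
            continue
        u, v = (nodes[n] for n in COW_EDGES[label])
        bow = np.asarray(config.bows[label], dtype=float)
        control = (u + v) / 2.0 + bow + rng.normal(0.0, config.bow_jitter_sd, 3)
        line = _bezier(u, control, v, config.sample_step)
        lo, hi = (
            config.normal_ranges[label] if status == NORMAL else config.hypoplastic_range
        )
        diameter = float(rng.uniform(lo, hi))
        edges[label] = SegmentSpec(label, line, diameter, status)
    context: list[tuple[np.ndarray, float]] = []
    if config.context_vessels:
        for node_name, direction, length, diameter in DEFAULT_CONTEXT_STUBS:
            for side_flip in ((1.0,) if node_name == "BA-top" else (1.0, -1.0)):
                name = node_name if side_flip > 0 else node_name.replace("-L", "-R")
                u = np.asarray(direction, dtype=float) * np.array([side_flip, 1.0, 1.0])
                u = u + rng.normal(0.0, 0.08, 3)
                u /= np.linalg.norm(u)
                start = nodes[name]
                if node_name == "ICA-T-L" and direction[1] < 0:
                    # carotid trunk runs through the PcoA-ICA bifurcation
                    via = nodes["PcoA-ICA-L" if side_flip > 0 else "PcoA-ICA-R"]
                    u2 = via - start
                    u2 = u2 / np.linalg.norm(u2)
                    line = np.vstack([start, via, via + (u2 + np.array([0, 0, -0.4])) /
                                      np.linalg.norm(u2 + np.array([0, 0, -0.4])) * length])
                else:
                    line = np.vstack([start, start + u * length])
                context.append((_resample_dense(line, config.sample_step), diameter))
    return GroundTruthGraph(
        nodes=nodes,
        edges=edges,
        variant=(variant.anterior, variant.posterior),
        context_vessels=context,
    )


def _resample_dense(line: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(s[-1] / step)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, line[:, k]) for k in range(3)])


def rasterize(
    gt: GroundTruthGraph,
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing: float | np.ndarray = 0.5,
    noise: NoiseSpec | None = None,
    origin: np.ndarray | None = None,
) -> Volume:
    """Render the ground-truth graph as a bright-lumen volume.

    Voxels whose center lies within a segment's tube radius receive the
    lumen peak intensity; everything is smoothed by a Gaussian of
    ``pv_sigma_mm`` (partial-volume surrogate), Gaussian noise is added,
    and intensities are clipped to be non-negative.  Aplastic segments
    contribute nothing.  By default the volume is centered on the node
    centroid.
    """
    noise = noise or NoiseSpec()
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive per axis")
    shape = tuple(int(s) for s in shape)
    if origin is None:
        centroid = np.mean([gt.nodes[n] for n in COW_NODE_NAMES], axis=0)
        origin = centroid - (np.asarray(shape) - 1) * spacing / 2.0
    origin = np.asarray(origin, dtype=float).reshape(3)
    world_max = origin + (np.asarray(shape) - 1) * spacing

    lumen = np.zeros(shape)

    def paint_tube(polyline: np.ndarray, r: float) -> None:
        dense = _resample_dense(polyline, 0.1)
        lo_idx = np.maximum(np.floor((dense.min(axis=0) - r - origin) / spacing).astype(int) - 1, 0)
        hi_idx = np.minimum(
            np.ceil((dense.max(axis=0) + r - origin) / spacing).astype(int) + 1,
            np.asarray(shape) - 1,
        )
        if np.any(hi_idx < lo_idx):
            return
        ax = [np.arange(lo_idx[k], hi_idx[k] + 1) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        centers = origin + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * spacing
        dist, _ = cKDTree(dense).query(centers, distance_upper_bound=r + 0.2)
        inside = (dist <= r).reshape(gx.shape)
        sub = lumen[lo_idx[0] : hi_idx[0] + 1, lo_idx[1] : hi_idx[1] + 1, lo_idx[2] : hi_idx[2] + 1]
        np.maximum(sub, np.where(inside, noise.lumen_peak, 0.0), out=sub)

    for label in SEGMENT_LABELS:
        seg = gt.edges[label]
        if seg.status == APLASTIC:
            continue
        if np.any(seg.centerline < origin) or np.any(seg.centerline > world_max):
            raise ValueError(f"centerline of segment {label} lies outside the field of view")
        paint_tube(seg.centerline, seg.radius)
    for line, diameter in gt.context_vessels:
        # context vessels are scenery: silently clipped to the field of view
        keep = np.all((line >= origin) & (line <= world_max), axis=1)
        if keep.sum() >= 2:
            paint_tube(line[keep], diameter / 2.0)

    image = np.where(lumen > 0, lumen, noise.background_mean)
    if noise.pv_sigma_mm > 0:
        image = gaussian_filter(image, sigma=noise.pv_sigma_mm / spacing)
    rng = np.random.default_rng(noise.seed)
    if noise.background_sd > 0:
        image = image + rng.normal(0.0, noise.background_sd, shape)
    return Volume(data=np.clip(image, 0.0, None), spacing=spacing, origin=origin)


def simulate_case(
    seed: int,
    prevalence: PrevalenceConfig | None = None,
    geometry: GeometryConfig | None = None,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing: float = 0.5,
) -> tuple[Volume, GroundTruthGraph]:
    """Draw a variant, realize its geometry, and render one phantom case."""
    prevalence = prevalence or PrevalenceConfig()
    geometry = geometry or GeometryConfig()
    ss = np.random.SeedSequence(seed)
    s_var, s_geom, s_noise = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))
    variant = sample_variant(prevalence, s_var)
    gt = build_geometry(variant, geometry, s_geom)
    base = noise or NoiseSpec()
    case_noise = NoiseSpec(
        background_mean=base.background_mean,
        background_sd=base.background_sd,
        lumen_peak=base.lumen_peak,
        pv_sigma_mm=base.pv_sigma_mm,
        seed=s_noise,
    )
    vol = rasterize(gt, shape=shape, spacing=spacing, noise=case_noise)
    return vol, gt
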