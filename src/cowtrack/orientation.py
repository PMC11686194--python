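"""Orientation-field estimation on a Cartesian grid covering the CoW.

At every node of a 0.5 mm grid, a provider produces a normalized spherical
scalar field whose two strongest well-separated maxima are the local
artery direction pair (d1, d2) and whose normalized entropy quantifies
confidence: entropy near 0 inside an artery lumen, near 1 outside.

Two providers are available:

* :class:`MatchedFilterProvider` — the deterministic image-driven
  estimator: multi-scale spherical patch projection with per-scale
  standardization, vertex-wise max aggregation, and L1 normalization.
* :class:`OracleOrientationProvider` — a ground-truth-driven test double
  emitting sharply two-lobed fields along the local centerline tangent
  inside artery tubes and uniform fields elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import sphere
from .phantom import APLASTIC, GroundTruthGraph
from .sphere import IcosphereMesh, make_icosphere
from .volume import Volume

DEFAULT_SCALES_MM: tuple[float, ...] = (1.0, 2.0, 5.0, 7.0, 10.0)
AXIS_NAMES = ("x", "y", "z")


@dataclass(eq=False)
class CartesianGrid:
    """Axis-aligned lattice of world points: origin + index * spacing (mm)."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.shape = tuple(int(s) for s in self.shape)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be at least 1 per axis")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def world_max(self) -> np.ndarray:
        return self.origin + (np.asarray(self.shape) - 1) * self.spacing

    def node_positions(self) -> np.ndarray:
        """All node world positions, C-ordered, shape (n_nodes, 3)."""
        ax = [self.origin[k] + self.spacing[k] * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def matches(self, other: "CartesianGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )


def build_grid(
    landmarks: np.ndarray,
    margin: float = 10.0,
    spacing: float = 0.5,
    volume: Volume | None = None,
    projection_margin: float = 0.0,
) -> CartesianGrid:
    """Grid over the landmark bounding box expanded by ``margin`` mm.

    When a volume is given, every grid node must keep ``projection_margin``
    mm of clearance to the volume boundary (so that spherical patches of
    the largest scale can be sampled); a violating axis raises.
    """
    pts = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if pts.size == 0:
        raise ValueError("need at least one landmark to build a grid")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    n = np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1
    grid = CartesianGrid(origin=lo, spacing=np.full(3, float(spacing)), shape=tuple(n))
    if volume is not None:
        vmin = volume.world_min + projection_margin
        vmax = volume.world_max - projection_margin
        for k in range(3):
            if grid.origin[k] < vmin[k] or grid.world_max[k] > vmax[k]:
                raise ValueError(
                    f"grid exceeds the usable volume extent along axis "
                    f"{AXIS_NAMES[k]} (projection margin {projection_margin} mm)"
                )
    return grid


@dataclass
class OrientationField:
    """Per-node direction pair, entropy, and degeneracy flag on a grid.

    ``d1``/``d2`` rows are NaN where the spherical field was degenerate
    (no admissible direction pair); entropy is defined everywhere.
    """

    grid: CartesianGrid
    d1: np.ndarray
    d2: np.ndarray
    entropy: np.ndarray
    degenerate: np.ndarray
    provider_name: str = ""
    scales_mm: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = self.grid.n_nodes
        for name in ("d1", "d2"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(n, 3)
            setattr(self, name, arr)
        self.entropy = np.asarray(self.entropy, dtype=float).reshape(n)
        self.degenerate = np.asarray(self.degenerate, dtype=bool).reshape(n)
        ok = ~self.degenerate
        if np.any((self.entropy < -1e-9) | (self.entropy > 1 + 1e-9)):
            raise ValueError("entropy must lie in [0, 1] at every node")
        norms = np.linalg.norm(self.d1[ok], axis=1)
        if ok.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("non-degenerate nodes must carry unit direction vectors")

    def save(self, path) -> None:
        path = str(path)
        np.savez_compressed(
            path, d1=self.d1, d2=self.d2, entropy=self.entropy, degenerate=self.degenerate
        )
        sidecar = {
            "origin_mm": list(self.grid.origin),
            "spacing_mm": list(self.grid.spacing),
            "shape": list(self.grid.shape),
            "provider": self.provider_name,
            "scales_mm": list(self.scales_mm),
        }
        with open(path.removesuffix(".npz") + ".json", "w") as fh:
            json.dump(sidecar, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "OrientationField":
        path = str(path)
        with open(path.removesuffix(".npz") + ".json") as fh:
            meta = json.load(fh)
        grid = CartesianGrid(meta["origin_mm"], meta["spacing_mm"], tuple(meta["shape"]))
        arrs = np.load(path)
        return cls(
            grid=grid,
            d1=arrs["d1"],
            d2=arrs["d2"],
            entropy=arrs["entropy"],
            degenerate=arrs["degenerate"],
            provider_name=meta.get("provider", ""),
            scales_mm=tuple(meta.get("scales_mm", ())),
        )


# ---------------------------------------------------------------------------
# providers


class MatchedFilterProvider:
    """Image-driven spherical orientation fields via radial mean filtering."""

    name = "matched_filter"

    def __init__(
        self,
        volume: Volume,
        mesh: IcosphereMesh | None = None,
        scales_mm: tuple[float, ...] = DEFAULT_SCALES_MM,
        n_radial: int = 8,
        smoothing_passes: int = 2,
        antipodal_max_deg: float | None = 45.0,
    ) -> None:
        self.volume = volume
        self.mesh = mesh if mesh is not None else make_icosphere(3)
        self.scales_mm = tuple(float(s) for s in scales_mm)
        self.n_radial = int(n_radial)
        self.smoothing_passes = int(smoothing_passes)
        #: a tube-like response has near-antipodal maxima; direction pairs
        #: further than this from antipodal (e.g. both maxima converging on
        #: a neighbouring bright artery) are treated as degenerate
        self.antipodal_max_deg = antipodal_max_deg

    def fields(self, points: np.ndarray) -> np.ndarray:
        """Normalized per-point spherical fields, shape (n_points, n_vertices)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        per_scale = [
            sphere.standardize_values(
                sphere.project_patch_batch(self.volume, points, r, self.mesh, self.n_radial)
            )
            for r in self.scales_mm
        ]
        agg = np.stack(per_scale).max(axis=0)
        if self.smoothing_passes > 0:
            agg = sphere.smooth_values(agg, self.mesh, self.smoothing_passes)
        total = agg.sum(axis=1, keepdims=True)
        uniform = 1.0 / self.mesh.n_vertices
        return np.where(total > 0, agg / np.where(total > 0, total, 1.0), uniform)


class OracleOrientationProvider:
    """Ground-truth orientation fields: two-lobed along tangents in tubes.

    Inside a segment's capture tube — distance to the centerline at most
    max(tube radius, ``capture_min_mm``) — the field is a Watson-like
    two-lobed bump exp(kappa * ((v . t)^2 - 1)) along the local tangent t;
    contributions from overlapping tubes add (a node inside two arteries
    sees a four-lobed field).  Everywhere else the field is uniform.  The
    capture floor keeps sub-voxel hypoplastic tubes traversable.
    """

    name = "oracle"

    def __init__(
        self,
        gt: GroundTruthGraph,
        mesh: IcosphereMesh | None = None,
        kappa: float = 20.0,
        capture_min_mm: float = 0.75,
    ) -> None:
        self.gt = gt
        self.mesh = mesh if mesh is not None else make_icosphere(3)
        self.kappa = float(kappa)
        self.capture_min_mm = float(capture_min_mm)
        self.scales_mm: tuple[float, ...] = ()
        self._segments = []
        tubes = [
            (label, seg.centerline, seg.radius)
            for label, seg in gt.edges.items()
            if seg.status != APLASTIC
        ]
        tubes += [
            (f"context-{i}", line, diameter / 2.0)
            for i, (line, diameter) in enumerate(gt.context_vessels)
        ]
        for label, pts, radius in tubes:
            tang = np.gradient(pts, axis=0)
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            self._segments.append(
                (label, cKDTree(pts), tang, max(radius, self.capture_min_mm))
            )

    def fields(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros((len(points), self.mesh.n_vertices))
        verts = self.mesh.vertices
        for _, tree, tang, capture in self._segments:
            dist, idx = tree.query(points, distance_upper_bound=capture + 1e-9)
            inside = np.isfinite(dist) & (dist <= capture)
            if not inside.any():
                continue
            t = tang[idx[inside]]
            cos2 = (verts @ t.T) ** 2  # (V, M)
            out[inside] += np.exp(self.kappa * (cos2.T - 1.0))
        total = out.sum(axis=1, keepdims=True)
        uniform = 1.0 / self.mesh.n_vertices
        return np.where(total > 0, out / np.where(total > 0, total, 1.0), uniform)


def make_provider(
    name: str,
    volume: Volume | None = None,
    gt: GroundTruthGraph | None = None,
    **kwargs,
):
    """Instantiate a provider by name ('matched_filter' or 'oracle')."""
    if name == "matched_filter":
        if volume is None:
            raise ValueError("matched_filter provider requires a volume")
        return MatchedFilterProvider(volume, **kwargs)
    if name == "oracle":
        if gt is None:
            raise ValueError("oracle provider requires a ground-truth graph")
        return OracleOrientationProvider(gt, **kwargs)
    raise ValueError(f"unknown provider {name!r}")


# ---------------------------------------------------------------------------
# batched maxima extraction and field estimation


def _top2_batch(
    values: np.ndarray, mesh: IcosphereMesh, min_separation_deg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized equivalent of :func:`cowtrack.sphere.top2_directions`."""
    n, nv = values.shape
    padded = np.concatenate([values, np.full((n, 1), -np.inf)], axis=1)
    neigh_max = padded[:, mesh.adjacency].max(axis=2)
    is_max = values > neigh_max
    d1 = np.full((n, 3), np.nan)
    d2 = np.full((n, 3), np.nan)
    degen = np.ones(n, dtype=bool)
    cos_thresh = np.cos(np.deg2rad(min_separation_deg))
    verts = mesh.vertices
    for i in np.flatnonzero(is_max.sum(axis=1) >= 2):
        idx = np.flatnonzero(is_max[i])
        order = idx[np.lexsort((idx, -values[i, idx]))]
        v1 = verts[order[0]]
        for j in order[1:]:
            if float(v1 @ verts[j]) <= cos_thresh + 1e-12:
                d1[i], d2[i] = v1, verts[j]
                degen[i] = False
                break
    return d1, d2, degen


def estimate_field(
    volume: Volume | None,
    grid: CartesianGrid,
    provider,
    batch_size: int = 500,
    min_separation_deg: float = 60.0,
) -> OrientationField:
    """Evaluate the provider at every grid node, in batches.

    Batching is performance-only: results are independent of batch size.
    Degenerate nodes get entropy from their (uniform or near-uniform)
    field and NaN directions.
    """
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    points = grid.node_positions()
    n = len(points)
    d1 = np.full((n, 3), np.nan)
    d2 = np.full((n, 3), np.nan)
    ent = np.empty(n)
    degen = np.ones(n, dtype=bool)
    mesh = provider.mesh
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        try:
            fields = provider.fields(points[sl])
        except ValueError as err:
            raise ValueError(f"orientation estimation failed in node batch starting at "
                             f"{points[sl][0]}: {err}") from err
        ent[sl] = sphere.entropy_rows(fields)
        d1[sl], d2[sl], degen[sl] = _top2_batch(fields, mesh, min_separation_deg)
    gate = getattr(provider, "antipodal_max_deg", None)
    if gate is not None:
        cos_to_antipode = -(d1 * d2).sum(axis=1)
        non_tubular = ~degen & (cos_to_antipode < np.cos(np.deg2rad(gate)))
        d1[non_tubular] = np.nan
        d2[non_tubular] = np.nan
        degen |= non_tubular
    return OrientationField(
        grid=grid,
        d1=d1,
        d2=d2,
        entropy=np.clip(ent, 0.0, 1.0),
        degenerate=degen,
        provider_name=getattr(provider, "name", type(provider).__name__),
        scales_mm=tuple(getattr(provider, "scales_mm", ())),
    )
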