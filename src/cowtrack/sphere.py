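"""Spherical scalar fields on icosphere meshes.

Local artery orientation is represented as a scalar field on the unit
sphere: image intensities around a point are projected radially onto the
sphere's surface, per-scale fields are fused by a vertex-wise maximum,
and the two strongest well-separated local maxima give the (unsigned)
artery direction pair.  The spread of the field is quantified by the
normalized Shannon entropy

    H(f) = -(1 / ln |V|) * sum_v f(v) ln f(v),

which is 1 for a uniform field (no directional signal, i.e. the point is
not inside an artery lumen) and 0 for a one-hot field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .volume import Volume


class DegenerateFieldError(ValueError):
    """Raised when a spherical field has fewer than two admissible maxima."""


@dataclass(frozen=True)
class IcosphereMesh:
    """Triangulated unit sphere by recursive icosahedron subdivision.

    ``vertices`` are unit vectors (the direction set V), ``faces`` index
    triples, ``adjacency`` a (V, max_degree) padded int array of one-ring
    neighbours with -1 fill, and ``degree`` the per-vertex neighbour count.
    """

    level: int
    vertices: np.ndarray
    faces: np.ndarray
    adjacency: np.ndarray
    degree: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def export(self, path) -> None:
        """Write the mesh as OFF/PLY (format chosen by file extension)."""
        trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False).export(str(path))


def make_icosphere(level: int = 3) -> IcosphereMesh:
    """Build an icosphere with 10 * 4**level + 2 unit-norm vertices."""
    if level < 0:
        raise ValueError(f"subdivision level must be >= 0, got {level}")
    mesh = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.asarray(mesh.faces, dtype=int)

    nv = len(verts)
    neigh: list[set[int]] = [set() for _ in range(nv)]
    for a, b, c in faces:
        neigh[a].update((b, c))
        neigh[b].update((a, c))
        neigh[c].update((a, b))
    degree = np.array([len(s) for s in neigh], dtype=int)
    adj = np.full((nv, degree.max()), -1, dtype=int)
    for i, s in enumerate(neigh):
        adj[i, : len(s)] = sorted(s)
    return IcosphereMesh(level=level, vertices=verts, faces=faces, adjacency=adj, degree=degree)


@dataclass
class SphericalField:
    """Per-vertex scalar values on an icosphere mesh."""

    mesh: IcosphereMesh
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("field length does not match mesh vertex count")

    def to_csv(self, path) -> None:
        arr = np.column_stack([np.arange(len(self.values)), self.values])
        np.savetxt(str(path), arr, delimiter=",", header="vertex,value", comments="")


# ---------------------------------------------------------------------------
# projection


def project_patch_batch(
    volume: Volume,
    centers: np.ndarray,
    radius: float,
    mesh: IcosphereMesh,
    n_radial: int = 8,
) -> np.ndarray:
    """Project spherical image patches for many centers at once.

    For each center and each mesh vertex direction v, the patch value is the
    mean of trilinearly interpolated intensities at the radii (j/k) * radius,
    j = 1..k, along v.  Returns an (n_centers, n_vertices) array.
    """
    if radius <= 0:
        raise ValueError(f"patch radius must be positive, got {radius}")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    inside = volume.contains(centers, margin_mm=radius)
    if not np.all(inside):
        bad = centers[~inside][0]
        raise ValueError(
            f"patch center {bad} is closer than the patch radius {radius} mm "
            "to the volume boundary"
        )
    radii = (np.arange(1, n_radial + 1) / n_radial) * radius
    # (n_centers, n_vertices, n_radial, 3) sample positions
    pts = centers[:, None, None, :] + mesh.vertices[None, :, None, :] * radii[None, None, :, None]
    vals = volume.sample(pts.reshape(-1, 3)).reshape(len(centers), mesh.n_vertices, n_radial)
    return vals.mean(axis=2)


def project_patch(
    volume: Volume,
    center: np.ndarray,
    radius: float,
    mesh: IcosphereMesh,
    n_radial: int = 8,
) -> SphericalField:
    """Project the image patch of one center onto the sphere (one scale)."""
    vals = project_patch_batch(volume, np.asarray(center, dtype=float)[None, :], radius, mesh, n_radial)
    return SphericalField(mesh=mesh, values=vals[0], normalized=False)


# ---------------------------------------------------------------------------
# aggregation, normalization, entropy


def standardize_values(values: np.ndarray) -> np.ndarray:
    """Z-score across vertices, then shift to be non-negative.

    Constant fields (zero variance) standardize to all-zero: they carry no
    directional information at that scale.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (values - values.mean(axis=-1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    return out - out.min(axis=-1, keepdims=True)


def smooth_values(values: np.ndarray, mesh: IcosphereMesh, n_passes: int = 1) -> np.ndarray:
    """One-ring Laplacian smoothing of per-vertex values (rows).

    Each pass averages a vertex with the mean of its one-ring; regularizes
    the noisy radial-mean response of the matched filter the way a learned
    spherical regressor produces inherently smooth fields.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    for _ in range(n_passes):
        padded = np.concatenate([values, np.zeros((len(values), 1))], axis=1)
        ring = padded[:, mesh.adjacency].sum(axis=2) / mesh.degree
        values = 0.5 * values + 0.5 * ring
    return values


def aggregate_scales(fields: list[SphericalField]) -> SphericalField:
    """Fuse per-scale fields by a vertex-wise maximum of standardized values."""
    if not fields:
        raise ValueError("need at least one per-scale field")
    mesh = fields[0].mesh
    for f in fields[1:]:
        if f.mesh is not mesh and f.mesh.n_vertices != mesh.n_vertices:
            raise ValueError("all per-scale fields must share one mesh")
    stacked = np.stack([standardize_values(f.values) for f in fields])
    return SphericalField(mesh=mesh, values=stacked.max(axis=0), normalized=False)


def normalize_field(field: SphericalField) -> SphericalField:
    """L1-normalize to a distribution; the all-zero field becomes uniform."""
    vals = field.values
    if np.any(vals < 0):
        raise ValueError("spherical field values must be non-negative")
    total = vals.sum()
    if total == 0:
        out = np.full_like(vals, 1.0 / len(vals))
    else:
        out = vals / total
    return SphericalField(mesh=field.mesh, values=out, normalized=True)


def entropy(field: SphericalField) -> float:
    """Normalized Shannon entropy of a distribution over the vertex set.

    Returns a value in [0, 1]: 1 for the uniform field, 0 for one-hot.
    The convention 0 * ln 0 = 0 applies.
    """
    if not field.normalized:
        raise ValueError("entropy requires an L1-normalized field")
    return float(entropy_rows(field.values[None, :])[0])


def entropy_rows(p: np.ndarray) -> np.ndarray:
    """Normalized entropy of each row of a stack of distributions."""
    p = np.asarray(p, dtype=float)
    nv = p.shape[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1) / np.log(nv)


# ---------------------------------------------------------------------------
# maxima extraction


def local_maxima(field: SphericalField) -> np.ndarray:
    """Indices of vertices strictly greater than all one-ring neighbours."""
    mesh = field.mesh
    vals = field.values
    padded = np.append(vals, -np.inf)  # -1 fill indexes the sentinel
    neigh_max = padded[mesh.adjacency].max(axis=1)
    return np.flatnonzero(vals > neigh_max)


def top2_directions(
    field: SphericalField, min_separation_deg: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """The two strongest well-separated mesh-local maxima, as unit vectors.

    Maxima are ordered by descending value, ties by lowest vertex index; the
    second direction must be at least ``min_separation_deg`` away from the
    first.  Raises :class:`DegenerateFieldError` when no admissible pair
    exists (e.g. a uniform field).
    """
    idx = local_maxima(field)
    if len(idx) < 2:
        raise DegenerateFieldError("fewer than 2 mesh-local maxima")
    order = idx[np.lexsort((idx, -field.values[idx]))]
    cos_thresh = np.cos(np.deg2rad(min_separation_deg))
    d1 = field.mesh.vertices[order[0]]
    for j in order[1:]:
        d2 = field.mesh.vertices[j]
        if float(d1 @ d2) <= cos_thresh + 1e-12:
            return d1.copy(), d2.copy()
    raise DegenerateFieldError(
        f"no second maximum separated by >= {min_separation_deg} degrees"
    )
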