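"""Minimal-path extraction of the seven CoW segments.

Every segment of the complete-CoW template is extracted as a Dijkstra
shortest path on the 26-connected Cartesian grid between its two snapped
bifurcation landmarks — always, even when the underlying artery is
aplastic (the anatomical prior forces an overcomplete reconstruction and
leaves the normal-vs-hypo/aplastic decision to the classifier).

Edge weights derive from node costs by trapezoidal averaging times the
Euclidean step length, w(x, y) = (c(x) + c(y))/2 * ||y - x|| + eps, which
makes cost accumulation resolution-consistent and anisotropy-aware; the
small eps keeps all weights strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .costs import NEIGHBOUR_OFFSETS, CostField
from .landmarks import LandmarkSet
from .orientation import CartesianGrid
from .template import CowTemplate

EDGE_EPSILON_MM = 1e-6


@dataclass
class ArteryPath:
    """An extracted segment path: ordered grid nodes in world mm."""

    label: str
    points: np.ndarray
    node_indices: np.ndarray
    total_cost: float
    cost_kind: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.node_indices = np.asarray(self.node_indices, dtype=int).reshape(-1)
        if self.total_cost < 0:
            raise ValueError("accumulated cost must be non-negative")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def snap(point_mm: np.ndarray, grid: CartesianGrid) -> int:
    """Nearest lattice node (flat index); exact midpoints go to the lower index."""
    point_mm = np.asarray(point_mm, dtype=float).reshape(3)
    t = (point_mm - grid.origin) / grid.spacing
    if np.any(t < -0.5 - 1e-9) or np.any(t > np.asarray(grid.shape) - 0.5 + 1e-9):
        raise ValueError(f"point {point_mm} lies outside the grid bounding box")
    idx = np.ceil(t - 0.5).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    return int(np.ravel_multi_index(tuple(idx), grid.shape))


def build_lattice_graph(cost: CostField) -> csr_matrix:
    """Symmetric sparse 26-connectivity graph weighted by the tracking cost."""
    shape = cost.grid.shape
    spacing = cost.grid.spacing
    c = cost.tracking.reshape(shape)
    lin = np.arange(int(np.prod(shape))).reshape(shape)
    rows, cols, weights = [], [], []
    # half the offsets suffice for an undirected graph
    for off in NEIGHBOUR_OFFSETS[: len(NEIGHBOUR_OFFSETS) // 2]:
        src = tuple(slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, shape))
        dst = tuple(slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, shape))
        step = float(np.linalg.norm(off * spacing))
        w = 0.5 * (c[src] + c[dst]) * step + EDGE_EPSILON_MM
        rows.append(lin[src].ravel())
        cols.append(lin[dst].ravel())
        weights.append(w.ravel())
    n = int(np.prod(shape))
    return csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def dijkstra(
    cost: CostField,
    seed_node: int,
    sink_node: int,
    graph: csr_matrix | None = None,
    label: str = "",
) -> ArteryPath:
    """Minimal-total-weight 26-connected path between two grid nodes."""
    if seed_node == sink_node:
        raise ValueError("seed and sink must differ")
    if graph is None:
        graph = build_lattice_graph(cost)
    dist, pred = _csgraph_dijkstra(
        graph, directed=False, indices=seed_node, return_predecessors=True
    )
    if not np.isfinite(dist[sink_node]):
        raise ValueError("sink is unreachable from seed")  # cannot occur on a full lattice
    chain = [sink_node]
    while chain[-1] != seed_node:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    idx = np.asarray(chain, dtype=int)
    coords = np.column_stack(np.unravel_index(idx, cost.grid.shape))
    points = cost.grid.origin + coords * cost.grid.spacing
    return ArteryPath(
        label=label,
        points=points,
        node_indices=idx,
        total_cost=float(dist[sink_node]),
        cost_kind=cost.kind,
    )


def extract_cow(
    cost: CostField,
    landmarks: LandmarkSet,
    template: CowTemplate | None = None,
) -> dict[str, ArteryPath]:
    """One shortest path per template segment between snapped landmarks."""
    template = template or CowTemplate()
    node_idx = {}
    for name, point in landmarks.points.items():
        try:
            node_idx[name] = snap(point, cost.grid)
        except ValueError as err:
            raise ValueError(f"landmark {name}: {err}") from err
    graph = build_lattice_graph(cost)
    paths: dict[str, ArteryPath] = {}
    for segment_label, (u, v) in template.edges.items():
        paths[segment_label] = dijkstra(
            cost, node_idx[u], node_idx[v], graph=graph, label=segment_label
        )
    return paths


# ---------------------------------------------------------------------------
# I/O


def paths_to_csv(paths: dict[str, ArteryPath], path) -> None:
    rows = ["label,x,y,z"]
    for label in sorted(paths):
        for p in paths[label].points:
            rows.append(f"{label},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def paths_from_csv(path) -> dict[str, np.ndarray]:
    """Read per-label polylines back from CSV (geometry only)."""
    out: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError("expected a 'label,x,y,z' header")
        for line in fh:
            label, x, y, z = line.strip().split(",")
            out.setdefault(label, []).append([float(x), float(y), float(z)])
    return {k: np.asarray(v) for k, v in out.items()}
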