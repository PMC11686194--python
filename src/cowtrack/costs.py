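"""Node-wise cost functions for minimal-path artery tracking.

Four costs on the Cartesian grid, all low inside the artery lumen and
high outside:

* orientation consensus — half of one minus the mean pairwise cosine
  similarity of the (unordered) direction pair between a node and its 26
  lattice neighbours, taking the better of the two label pairings;
* entropy — the normalized entropy of the node's spherical field;
* image — minus the trilinearly interpolated normalized intensity
  (tracking form 1 - I so Dijkstra sees non-negative weights);
* sum — the sum of the three.

Each :class:`CostField` carries the raw cost of its definition and a
non-negative "tracking" cost actually used for shortest paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .orientation import CartesianGrid, OrientationField
from .volume import Volume

COST_KINDS = ("orient", "entr", "img", "sum")

#: Lattice offsets of the 26-neighbourhood.
NEIGHBOUR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class CostField:
    """Per-node raw and non-negative tracking costs on a grid."""

    grid: CartesianGrid
    raw: np.ndarray
    tracking: np.ndarray
    kind: str
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in COST_KINDS:
            raise ValueError(f"unknown cost kind {self.kind!r}")
        n = self.grid.n_nodes
        self.raw = np.asarray(self.raw, dtype=float).reshape(n)
        self.tracking = np.asarray(self.tracking, dtype=float).reshape(n)
        if np.any(self.tracking < -1e-12):
            raise ValueError("tracking cost must be non-negative everywhere")

    def save(self, path) -> None:
        path = str(path)
        np.savez_compressed(path, raw=self.raw, tracking=self.tracking)
        sidecar = {
            "origin_mm": list(self.grid.origin),
            "spacing_mm": list(self.grid.spacing),
            "shape": list(self.grid.shape),
            "kind": self.kind,
            "offset": self.offset,
        }
        with open(path.removesuffix(".npz") + ".json", "w") as fh:
            json.dump(sidecar, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CostField":
        path = str(path)
        with open(path.removesuffix(".npz") + ".json") as fh:
            meta = json.load(fh)
        grid = CartesianGrid(meta["origin_mm"], meta["spacing_mm"], tuple(meta["shape"]))
        arrs = np.load(path)
        return cls(grid=grid, raw=arrs["raw"], tracking=arrs["tracking"],
                   kind=meta["kind"], offset=float(meta.get("offset", 0.0)))


# ---------------------------------------------------------------------------


def normalize_intensity(volume: Volume, lower_pct: float = 1.0, upper_pct: float = 99.0) -> Volume:
    """Map intensities linearly so the given percentiles hit [0, 1], clipped."""
    data = volume.data
    if np.ptp(data) == 0:
        raise ValueError("cannot normalize a constant volume")
    lo, hi = np.percentile(data, [lower_pct, upper_pct])
    if hi <= lo:
        raise ValueError("degenerate intensity percentiles")
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return Volume(data=out, spacing=volume.spacing, origin=volume.origin)


def cost_img(volume_normalized: Volume, grid: CartesianGrid) -> CostField:
    """Image cost -I(x) per node; tracking form 1 - I(x) in [0, 1]."""
    pts = grid.node_positions()
    if not np.all(volume_normalized.contains(pts)):
        bad = pts[~volume_normalized.contains(pts)][0]
        raise ValueError(f"grid node {bad} lies outside the volume")
    intensity = volume_normalized.sample(pts)
    return CostField(grid=grid, raw=-intensity, tracking=1.0 - intensity, kind="img", offset=1.0)


def cost_entropy(field: OrientationField, grid: CartesianGrid | None = None) -> CostField:
    """Entropy cost: the per-node normalized entropy itself."""
    if grid is not None and not field.grid.matches(grid):
        raise ValueError("orientation field grid does not match the requested grid")
    h = field.entropy.copy()
    return CostField(grid=field.grid, raw=h, tracking=h, kind="entr")


def cost_orient(field: OrientationField, grid: CartesianGrid | None = None) -> CostField:
    """Orientation-consensus cost over the 26-neighbourhood.

    For each node x and neighbour y the similarity term is half the better
    of the two pairings of the unordered direction pairs,
    0.5 * max(<d1x,d1y> + <d2x,d2y>, <d1x,d2y> + <d2x,d1y>); degenerate
    nodes or neighbours contribute 0.  The mean runs over the neighbours
    that exist (1/26 in the interior, 1/|N(x)| at grid boundaries) and the
    cost is 0.5 * (1 - mean), which lies in [0, 1].
    """
    if grid is not None and not field.grid.matches(grid):
        raise ValueError("orientation field grid does not match the requested grid")
    shape = field.grid.shape
    d1 = np.nan_to_num(field.d1).reshape(shape + (3,))
    d2 = np.nan_to_num(field.d2).reshape(shape + (3,))
    valid = (~field.degenerate).reshape(shape)

    sim_sum = np.zeros(shape)
    count = np.zeros(shape)
    for off in NEIGHBOUR_OFFSETS:
        src = tuple(
            slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, shape)
        )  # x positions with neighbour x+off in-grid
        dst = tuple(
            slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, shape)
        )  # the neighbour positions
        a = (d1[src] * d1[dst]).sum(-1) + (d2[src] * d2[dst]).sum(-1)
        b = (d1[src] * d2[dst]).sum(-1) + (d2[src] * d1[dst]).sum(-1)
        s = 0.5 * np.maximum(a, b)
        both = valid[src] & valid[dst]
        sim_sum[src] += np.where(both, s, 0.0)
        count[src] += 1.0
    mean_sim = sim_sum / count
    cost = 0.5 * (1.0 - mean_sim)
    cost = np.clip(cost, 0.0, 1.0).ravel()
    return CostField(grid=field.grid, raw=cost, tracking=cost, kind="orient")


def cost_sum(components: list[CostField]) -> CostField:
    """Sum of the orientation, entropy and image costs (raw and tracking)."""
    kinds = [c.kind for c in components]
    if sorted(kinds) != sorted(["orient", "entr", "img"]):
        raise ValueError(f"cost sum needs exactly one of each component kind, got {kinds}")
    grid = components[0].grid
    for c in components[1:]:
        if not c.grid.matches(grid):
            raise ValueError("cost components must share one grid")
    raw = np.sum([c.raw for c in components], axis=0)
    tracking = np.sum([c.tracking for c in components], axis=0)
    offset = float(np.sum([c.offset for c in components]))
    return CostField(grid=grid, raw=raw, tracking=tracking, kind="sum", offset=offset)


def build_cost(
    kind: str,
    orientation_field: OrientationField | None = None,
    volume_normalized: Volume | None = None,
    grid: CartesianGrid | None = None,
) -> CostField:
    """Build any of the four cost kinds from the available inputs."""
    if kind == "img":
        if volume_normalized is None or grid is None:
            raise ValueError("image cost needs a normalized volume and a grid")
        return cost_img(volume_normalized, grid)
    if orientation_field is None:
        raise ValueError(f"{kind} cost needs an orientation field")
    if kind == "entr":
        return cost_entropy(orientation_field, grid)
    if kind == "orient":
        return cost_orient(orientation_field, grid)
    if kind == "sum":
        if volume_normalized is None:
            raise ValueError("sum cost needs a normalized volume")
        return cost_sum(
            [
                cost_orient(orientation_field, grid),
                cost_entropy(orientation_field, grid),
                cost_img(volume_normalized, orientation_field.grid),
            ]
        )
    raise ValueError(f"unknown cost kind {kind!r}")
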