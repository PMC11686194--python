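"""Shared fixtures: meshes, phantom cases, and precomputed pipeline bundles.

Everything is generated programmatically and deterministically; heavier
artifacts (orientation fields, cost fields, extracted paths) are built
once per session and shared across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import cowtrack as ct
from cowtrack import costs, tracking
from cowtrack.phantom import APLASTIC, GroundTruthGraph, NoiseSpec, SegmentSpec
from cowtrack.template import COW_EDGES, COW_NODE_NAMES, SEGMENT_LABELS


@pytest.fixture(scope="session")
def mesh1():
    return ct.make_icosphere(1)


@pytest.fixture(scope="session")
def mesh2():
    return ct.make_icosphere(2)


@pytest.fixture(scope="session")
def mesh3():
    return ct.make_icosphere(3)


def single_tube_gt(
    label: str = "ACA-A1-L",
    start=(-10.0, 0.0, 0.0),
    end=(10.0, 0.0, 0.0),
    diameter: float = 2.0,
) -> GroundTruthGraph:
    """A ground-truth graph with one straight rendered tube; the other six
    segments are aplastic.  Node positions are synthetic and chosen so the
    tube's endpoints coincide with its template nodes."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    nodes = {name: np.array([0.0, 14.0, 10.0]) + i * 0.5 for i, name in enumerate(COW_NODE_NAMES)}
    u, v = COW_EDGES[label]
    nodes[u], nodes[v] = start, end
    n = int(np.ceil(np.linalg.norm(end - start) / 0.2)) + 1
    t = np.linspace(0, 1, n)[:, None]
    line = start * (1 - t) + end * t
    status = "normal" if diameter >= 1.0 else "hypoplastic"
    edges = {}
    for seg_label in SEGMENT_LABELS:
        if seg_label == label:
            edges[seg_label] = SegmentSpec(seg_label, line, diameter, status)
        else:
            edges[seg_label] = SegmentSpec(seg_label, np.empty((0, 3)), 0.0, APLASTIC)
    return GroundTruthGraph(nodes=nodes, edges=edges, variant=("A", "P0"))


@pytest.fixture(scope="session")
def tube_case():
    """Straight 2 mm tube along +x in a mildly noisy volume (0.5 mm grid)."""
    gt = single_tube_gt()
    noise = NoiseSpec(background_mean=20, background_sd=3, lumen_peak=100, pv_sigma_mm=0.3, seed=7)
    vol = ct.rasterize(gt, shape=(96, 72, 72), spacing=0.5, noise=noise, origin=(-24.0, -18.0, -18.0))
    return vol, gt


@dataclass
class CaseBundle:
    vol: object
    gt: object
    lm: object
    grid: object
    field: object
    norm: object
    cost_orient: object
    paths: dict


def _oracle_bundle(seed: int, mesh) -> CaseBundle:
    vol, gt = ct.simulate_case(seed)
    lm = ct.LandmarkSet.from_ground_truth(gt)
    grid = ct.build_grid(lm.as_array(), margin=2.0, spacing=0.5, volume=vol)
    provider = ct.OracleOrientationProvider(gt, mesh=mesh)
    field = ct.estimate_field(vol, grid, provider, batch_size=4000)
    norm = costs.normalize_intensity(vol)
    c = costs.cost_orient(field)
    paths = tracking.extract_cow(c, lm)
    return CaseBundle(vol, gt, lm, grid, field, norm, c, paths)


@pytest.fixture(scope="session")
def oracle_bundle(mesh2):
    """One default phantom taken through the oracle-provider chain."""
    return _oracle_bundle(5, mesh2)
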