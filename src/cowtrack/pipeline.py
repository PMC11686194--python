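"""End-to-end orchestration: volume + landmarks → labelled CoW graph.

Stages: orientation-field estimation on a grid containing the CoW, cost
construction, shortest-path extraction of the seven template segments,
intensity-profile classification, and Lippert class assignment.  Every
run records its fully resolved configuration and per-stage timings; given
identical inputs, configuration and seed, the output graph is
bitwise-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, costs, orientation, phantom, tracking
from .landmarks import LandmarkSet
from .sphere import make_icosphere
from .template import SEGMENT_LABELS
from .volume import Volume


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run (round-trips via JSON)."""

    grid_margin_mm: float = 3.0
    grid_spacing_mm: float = 0.5
    scales_mm: tuple[float, ...] = orientation.DEFAULT_SCALES_MM
    mesh_level: int = 3
    n_radial: int = 8
    batch_size: int = 500
    min_separation_deg: float = 60.0
    provider: str = "matched_filter"
    cost_kind: str = "orient"
    rf_n_trees: int = 100
    rf_max_depth: int = 2
    rf_threshold: float = 0.5
    n_train_cases: int = 12
    seed: int = 0

    def to_json(self, path) -> None:
        obj = asdict(self)
        obj["scales_mm"] = list(self.scales_mm)
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = json.load(fh)
        obj["scales_mm"] = tuple(obj["scales_mm"])
        return cls(**obj)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def train_default_classifier(
    config: PipelineConfig,
    prevalence: phantom.PrevalenceConfig | None = None,
    geometry: phantom.GeometryConfig | None = None,
    noise: phantom.NoiseSpec | None = None,
):
    """Train the path classifier on ground-truth profiles of fresh phantoms."""
    profiles, labels = [], []
    ss = np.random.SeedSequence([config.seed, 7919])
    case_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(config.n_train_cases + 20)]
    i = 0
    while i < len(case_seeds) and (
        i < config.n_train_cases or len(set(labels)) < 2
    ):
        vol, gt = phantom.simulate_case(
            case_seeds[i], prevalence=prevalence, geometry=geometry, noise=noise
        )
        norm = costs.normalize_intensity(vol)
        p, l = classify.training_profiles_from_ground_truth(norm, gt)
        profiles.extend(p)
        labels.extend(l)
        i += 1
    return classify.train_rf(
        profiles,
        labels,
        n_trees=config.rf_n_trees,
        max_depth=config.rf_max_depth,
        seed=config.seed,
    )


def run_pipeline(
    volume: Volume | str | Path,
    landmarks: LandmarkSet | str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    model=None,
    truth: phantom.GroundTruthGraph | None = None,
) -> Path:
    """Run all stages and write artifacts into ``out_dir``.

    ``truth`` is required only for the oracle orientation provider.  When
    no classifier model is given, one is trained on synthetic phantoms
    under the run's seed.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(volume, Volume):
        volume = Volume.from_nifti(volume)
    if not isinstance(landmarks, LandmarkSet):
        landmarks = LandmarkSet.from_json(landmarks)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # grid + orientation field
    projection_margin = max(config.scales_mm) if config.provider == "matched_filter" else 0.0
    grid = orientation.build_grid(
        landmarks.as_array(),
        margin=config.grid_margin_mm,
        spacing=config.grid_spacing_mm,
        volume=volume,
        projection_margin=projection_margin,
    )
    mesh = make_icosphere(config.mesh_level)
    provider = orientation.make_provider(
        config.provider,
        volume=volume,
        gt=truth,
        mesh=mesh,
        **({"scales_mm": config.scales_mm, "n_radial": config.n_radial}
           if config.provider == "matched_filter" else {}),
    )
    field = orientation.estimate_field(
        volume, grid, provider,
        batch_size=config.batch_size,
        min_separation_deg=config.min_separation_deg,
    )
    field.save(out / "orientation.npz")
    timings["orientation_s"] = time.perf_counter() - t0

    # costs
    t1 = time.perf_counter()
    norm = costs.normalize_intensity(volume)
    cost = costs.build_cost(config.cost_kind, orientation_field=field, volume_normalized=norm)
    cost.save(out / f"cost_{config.cost_kind}.npz")
    timings["costs_s"] = time.perf_counter() - t1

    # tracking
    t2 = time.perf_counter()
    paths = tracking.extract_cow(cost, landmarks)
    paths_dir = out / "paths"
    paths_dir.mkdir(exist_ok=True)
    for seg_label, p in paths.items():
        tracking.paths_to_csv({seg_label: p}, paths_dir / f"{seg_label}.csv")
    timings["tracking_s"] = time.perf_counter() - t2

    # classification + graph
    t3 = time.perf_counter()
    if model is None:
        model = train_default_classifier(config)
    profiles = [classify.profile(paths[s], norm) for s in SEGMENT_LABELS]
    path_labels = classify.classify_paths(model, profiles, threshold=config.rf_threshold)
    labels = dict(zip(SEGMENT_LABELS, path_labels))
    graph = classify.CowGraph.build(landmarks, paths, labels)
    graph.to_json(out / "graph.json")
    graph.to_graphml(out / "graph.graphml")
    timings["classify_s"] = time.perf_counter() - t3

    config.to_json(out / "config.json")
    with open(out / "log.json", "w") as fh:
        json.dump(
            {
                "config_digest": config.digest(),
                "seed": config.seed,
                "grid_shape": list(grid.shape),
                "timings_s": {k: round(v, 3) for k, v in timings.items()},
            },
            fh,
            sort_keys=True,
            indent=1,
        )
    return out


def make_dataset(
    n_cases: int,
    out_dir: str | Path,
    seed: int = 0,
    prevalence: phantom.PrevalenceConfig | None = None,
    geometry: phantom.GeometryConfig | None = None,
    noise: phantom.NoiseSpec | None = None,
    shape: tuple[int, int, int] = (96, 96, 64),
    spacing: float = 0.5,
) -> Path:
    """Generate a directory of phantom cases with ground truth and a manifest."""
    if n_cases < 1:
        raise ValueError("need at least one case")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case_seeds = [
        int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n_cases)
    ]
    rows = []
    for i, cseed in enumerate(case_seeds):
        vol, gt = phantom.simulate_case(
            cseed, prevalence=prevalence, geometry=geometry, noise=noise,
            shape=shape, spacing=spacing,
        )
        stem = f"case_{i:04d}"
        vol.to_nifti(out / f"{stem}.nii.gz")
        gt.to_json(out / f"{stem}_truth.json")
        gt.centerlines_to_csv(out / f"{stem}_centerlines.csv")
        LandmarkSet.from_ground_truth(gt).to_json(out / f"{stem}_landmarks.json")
        row = {
            "case_id": stem,
            "seed": cseed,
            "anterior_class": gt.variant[0],
            "posterior_class": gt.variant[1],
        }
        for seg_label in SEGMENT_LABELS:
            row[f"status_{seg_label}"] = gt.edges[seg_label].status
            row[f"diameter_{seg_label}"] = gt.edges[seg_label].diameter
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
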