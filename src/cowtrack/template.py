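"""The complete circle-of-Willis template: 9 bifurcations, 7 segments.

The anatomical prior of the whole pipeline: every subject is assumed to
have landmarks for all nine bifurcations, and a path is extracted for all
seven segments, whether or not the underlying artery is developed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The nine bifurcation landmark names.
COW_NODE_NAMES: tuple[str, ...] = (
    "ICA-T-L",
    "ICA-T-R",
    "PcoA-ICA-L",
    "PcoA-ICA-R",
    "A1A2-L",
    "A1A2-R",
    "P1P2-L",
    "P1P2-R",
    "BA-top",
)

#: Segment label -> (seed node, sink node).
COW_EDGES: dict[str, tuple[str, str]] = {
    "ACA-A1-L": ("ICA-T-L", "A1A2-L"),
    "ACA-A1-R": ("ICA-T-R", "A1A2-R"),
    "AcoA": ("A1A2-L", "A1A2-R"),
    "PCA-P1-L": ("BA-top", "P1P2-L"),
    "PCA-P1-R": ("BA-top", "P1P2-R"),
    "PcoA-L": ("PcoA-ICA-L", "P1P2-L"),
    "PcoA-R": ("PcoA-ICA-R", "P1P2-R"),
}

#: Canonical segment order used everywhere (determinism of sampling etc.).
SEGMENT_LABELS: tuple[str, ...] = tuple(COW_EDGES)

#: Segments forming the anterior and posterior CoW sections.
ANTERIOR_SEGMENTS: tuple[str, ...] = ("ACA-A1-L", "ACA-A1-R", "AcoA")
POSTERIOR_SEGMENTS: tuple[str, ...] = ("PCA-P1-L", "PCA-P1-R", "PcoA-L", "PcoA-R")


@dataclass(frozen=True)
class CowTemplate:
    """Node names and segment connectivity of a complete CoW."""

    nodes: tuple[str, ...] = COW_NODE_NAMES
    edges: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(COW_EDGES))

    def __post_init__(self) -> None:
        for label, (u, v) in self.edges.items():
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {label} references unknown node ({u}, {v})")
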