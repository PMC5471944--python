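"""Synthetic STITCH/STRING-dialect fixtures.

Every module of the package is testable without downloading the real
databases: :func:`toy1` builds a small fixed graph whose shortest-path
structure is worked out by hand (and by exhaustive enumeration in the test
suite), and :func:`generate` emits seeded pseudo-random flat files in the
exact dialects the parsers consume.

TOY-1 layout (combined scores; every score also placed in the
``experimental`` channel so channel-weight machinery has something to act
on)::

    D (chemical) —0.9— A —0.8— M        D —0.2— M (weak direct edge)
    D —0.7— B,  B —0.9— M,  A —0.5— B
    E (chemical) —0.6— B
    C isolated

The direct D–M edge is deliberately NOT the lightest route (w = 0.8 vs
0.3 via A), exercising the direct-vs-shortest distinction in pair
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import (
    CHEM_CHEM_CHANNELS,
    CHEM_PROTEIN_CHANNELS,
    PROTEIN_CHANNELS,
    EvidenceEdge,
    EvidenceGraph,
)

#: Human-readable labels for the TOY-1 node ids.
TOY1_LABELS = {
    "CIDm00000004": "D",
    "CIDm00000005": "E",
    "9606.A": "A",
    "9606.B": "B",
    "9606.C": "C",
    "9606.M": "M",
}
TOY1_IDS = {label: raw for raw, label in TOY1_LABELS.items()}

_TOY1_EDGES = [
    ("D", "A", 0.9),
    ("A", "M", 0.8),
    ("D", "B", 0.7),
    ("B", "M", 0.9),
    ("A", "B", 0.5),
    ("D", "M", 0.2),
    ("E", "B", 0.6),
]


def toy1() -> EvidenceGraph:
    """The fixed six-node worked-example graph (see module docstring)."""
    graph = EvidenceGraph()
    for raw, label in TOY1_LABELS.items():
        graph.add_node(raw)
        graph.add_alias(label, raw)
    for lu, lv, s in _TOY1_EDGES:
        graph.add_edge(
            EvidenceEdge(
                TOY1_IDS[lu], TOY1_IDS[lv], {"experimental": s}, s
            )
        )
    return graph


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a pseudo-random fixture graph.

    ``edge_density`` is the probability that any admissible node pair gets
    an edge.  ``score_distribution`` maps channel names to ``(presence
    probability, mean score)``; each present channel draws a score uniformly
    on [0, 2·mean] ∩ [0.001, 1], quantized to the 1/1000 grid.  Channels not
    listed are absent.  The same ``(spec, seed)`` always produces
    byte-identical files.
    """

    n_proteins: int = 8
    n_chemicals: int = 2
    edge_density: float = 0.4
    score_distribution: tuple[tuple[str, float, float], ...] = (
        ("experimental", 0.7, 0.45),
        ("database", 0.4, 0.35),
        ("textmining", 0.6, 0.25),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if self.n_proteins < 0 or self.n_chemicals < 0:
            raise ValueError("node counts must be nonnegative")


MAX_EDGES = 10**6


def _node_names(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    proteins = [f"9606.P{i:04d}" for i in range(spec.n_proteins)]
    chemicals = [f"CIDm{i + 1:08d}" for i in range(spec.n_chemicals)]
    return proteins, chemicals


def _draw_scores(
    rng: np.random.Generator,
    spec: FixtureSpec,
    allowed: tuple[str, ...],
) -> tuple[dict[str, int], int]:
    channels: dict[str, int] = {}
    for name, p_present, mean in spec.score_distribution:
        if name not in allowed:
            continue
        if rng.random() < p_present:
            hi = min(2.0 * mean, 1.0)
            value = int(round(rng.uniform(0.001, hi) * 1000))
            channels[name] = max(value, 1)
    if channels:
        # noisy-OR of the sub-scores, on the integer grid
        complement = 1.0
        for v in channels.values():
            complement *= 1.0 - v / 1000.0
        combined = max(round((1.0 - complement) * 1000), 1)
    else:
        combined = int(rng.integers(1, 1001))
    return channels, combined


def generate(spec: FixtureSpec) -> dict[str, str]:
    """Generate flat-file text for a pseudo-random evidence graph.

    Returns the same section mapping as
    :func:`evidencenet.graph_io.write_flat_files` (keys ``protein_links``,
    ``chemical_protein_links``, ``chemical_chemical_links``), each file in
    its parser's dialect with protein–protein pairs listed in both orders as
    STRING does.
    """
    proteins, chemicals = _node_names(spec)
    n = len(proteins) + len(chemicals)
    if spec.edge_density * n * (n - 1) / 2 > MAX_EDGES:
        raise ValueError(
            f"spec would generate more than {MAX_EDGES} edges; refusing"
        )
    rng = np.random.default_rng(spec.seed)

    pp_rows = []
    for i, u in enumerate(proteins):
        for v in proteins[i + 1 :]:
            if rng.random() >= spec.edge_density:
                continue
            channels, combined = _draw_scores(rng, spec, PROTEIN_CHANNELS)
            scores = [
                str(channels.get(c, 0)) for c in PROTEIN_CHANNELS
            ] + [str(combined)]
            pp_rows.append(" ".join([u, v] + scores))
            pp_rows.append(" ".join([v, u] + scores))

    cp_rows = []
    for c in chemicals:
        for p in proteins:
            if rng.random() >= spec.edge_density:
                continue
            channels, combined = _draw_scores(rng, spec, CHEM_PROTEIN_CHANNELS)
            scores = [
                str(channels.get(ch, 0)) for ch in CHEM_PROTEIN_CHANNELS
            ] + [str(combined)]
            cp_rows.append(" ".join([c, p] + scores))

    cc_rows = []
    for i, c1 in enumerate(chemicals):
        for c2 in chemicals[i + 1 :]:
            if rng.random() >= spec.edge_density:
                continue
            channels, combined = _draw_scores(rng, spec, CHEM_CHEM_CHANNELS)
            scores = [
                str(channels.get(ch, 0)) for ch in CHEM_CHEM_CHANNELS
            ] + [str(combined)]
            cc_rows.append(" ".join([c1, c2] + scores))

    sections = {
        "protein_links": [
            "protein1 protein2 "
            + " ".join(PROTEIN_CHANNELS)
            + " combined_score"
        ]
        + pp_rows,
        "chemical_protein_links": [
            "chemical protein "
            + " ".join(CHEM_PROTEIN_CHANNELS)
            + " combined_score"
        ]
        + cp_rows,
        "chemical_chemical_links": [
            "chemical1 chemical2 "
            + " ".join(CHEM_CHEM_CHANNELS)
            + " combined_score"
        ]
        + cc_rows,
    }
    return {k: "\n".join(v) + "\n" for k, v in sections.items()}


def generate_graph(spec: FixtureSpec) -> EvidenceGraph:
    """Parse :func:`generate` output straight into an evidence graph."""
    from . import graph_io

    files = generate(spec)
    parts = [
        graph_io.parse_protein_links(
            files["protein_links"].splitlines(), "detailed"
        ),
        graph_io.parse_chemical_links(
            files["chemical_protein_links"].splitlines(), "chemical-protein"
        ),
        graph_io.parse_chemical_links(
            files["chemical_chemical_links"].splitlines(), "chemical-chemical"
        ),
    ]
    return graph_io.merge_graphs(parts)
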