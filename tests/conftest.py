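"""Shared fixtures and the brute-force path oracle.

The oracle enumerates ALL simple paths with :func:`networkx.all_simple_paths`
and scores them with its own closed-form edge weighting, independent of the
package's search code, so K-shortest-path results can be checked against an
exhaustive ground truth on small graphs.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from evidencenet.fixtures import TOY1_IDS, TOY1_LABELS, toy1
from evidencenet.graph import EvidenceEdge, EvidenceGraph


@pytest.fixture
def toy():
    return toy1()


@pytest.fixture
def ids():
    return TOY1_IDS


def label_path(nodes) -> str:
    """Compact label string like 'DAM' for a TOY-1 node sequence."""
    return "".join(TOY1_LABELS[n] for n in nodes)


# -- independent oracle ---------------------------------------------------


def oracle_effective_score(edge: EvidenceEdge, multipliers: dict) -> float:
    """Closed-form effective score, written independently of the package."""
    if all(m == 1.0 for m in multipliers.values()):
        return edge.reported_combined
    prod = 1.0
    for channel, s in edge.channel_scores.items():
        prod *= 1.0 - multipliers.get(channel, 1.0) * s
    return 1.0 - prod


def oracle_paths(
    graph: EvidenceGraph,
    src: str,
    dst: str,
    multipliers: dict | None = None,
    max_intermediates: int | None = None,
) -> list[tuple[float, tuple[str, ...]]]:
    """All simple src→dst paths, sorted by (weight, node sequence)."""
    multipliers = multipliers or {}
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for edge in graph.edges:
        s = oracle_effective_score(edge, multipliers)
        g.add_edge(edge.u, edge.v, w=1.0 - s)
    if src == dst:
        return [(0.0, (src,))]
    out = []
    for nodes in nx.all_simple_paths(g, src, dst):
        if max_intermediates is not None and len(nodes) - 2 > max_intermediates:
            continue
        # exact rational sum: float addition is not associative, and ordering
        # mathematically tied paths must not depend on summation order
        weight = sum(
            (Fraction(g.edges[a, b]["w"]) for a, b in zip(nodes, nodes[1:])),
            Fraction(0),
        )
        out.append((weight, tuple(nodes)))
    out.sort()
    return [(float(w), nodes) for w, nodes in out]


def random_graph(
    rng: np.random.Generator,
    n_proteins: int = 7,
    n_chemicals: int = 2,
    density: float = 0.35,
) -> EvidenceGraph:
    """Small random evidence graph with grid scores, for oracle sweeps."""
    nodes = [f"9606.P{i}" for i in range(n_proteins)] + [
        f"CIDm{i + 1:08d}" for i in range(n_chemicals)
    ]
    graph = EvidenceGraph()
    for n in nodes:
        graph.add_node(n)
    channels = ("experimental", "database", "textmining")
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if rng.random() >= density:
                continue
            scores = {
                c: round(rng.integers(1, 1000)) / 1000.0
                for c in channels
                if rng.random() < 0.6
            }
            combined = round(rng.integers(1, 1001)) / 1000.0
            graph.add_edge(EvidenceEdge(u, v, scores, combined))
    return graph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
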