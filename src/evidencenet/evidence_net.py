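"""Evidence-network assembly for drug–mediator pairs.

An evidence network is the sub-network of the chemical–protein evidence
graph obtained by merging the best-evidenced (weight-shortest) loopless
paths between a compound and a mediator gene.  Paths are accepted one at a
time, best first, until the supply is exhausted or the merged sub-network
holds at least ``N`` distinct nodes — a stopping condition, not a strict
floor, since the final path may push the node count past ``N``.  Paths with
more than ``max_intermediates`` genes between the endpoints are never
accepted: long chains of intermediaries carry little interpretive value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from .graph import AnnotationTable, EvidenceEdge, EvidenceGraph
from .pathfinding import (
    ChannelWeights,
    WeightedPath,
    WeightedView,
    iter_shortest_paths,
    shortest_path,
)

logger = logging.getLogger(__name__)

DEFAULT_N = 10
DEFAULT_MAX_INTERMEDIATES = 3


class PairCategory(str, Enum):
    """Drug–mediator relation class by intermediate-gene distance."""

    DIRECT = "direct"
    ONE = "1"
    TWO = "2"
    THREE = "3"
    UNREACHABLE = "unreachable"
    NOT_IN_DB = "not_in_db"


@dataclass
class EvidenceNetwork:
    """Merged sub-network linking source chemical(s) to a target mediator."""

    sources: frozenset[str]
    target: str
    paths: list[WeightedPath]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    isolated_nodes: frozenset[str] = frozenset()
    annotations: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    neighbor_labels: dict[str, str] = field(default_factory=dict)
    stop_reason: str = ""

    @property
    def nodes(self) -> set[str]:
        out = set(self.sources) | {self.target} | set(self.isolated_nodes)
        for path in self.paths:
            out.update(path.nodes)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:
        return (
            f"EvidenceNetwork({sorted(self.sources)} → {self.target}: "
            f"{len(self.paths)} paths, {self.n_nodes} nodes, "
            f"{len(self.edges)} edges)"
        )


def _edges_of(paths: list[WeightedPath]) -> dict[tuple[str, str], float]:
    edges: dict[tuple[str, str], float] = {}
    for path in paths:
        for (a, b), s in zip(zip(path.nodes, path.nodes[1:]), path.edge_scores):
            pair = (a, b) if a <= b else (b, a)
            edges[pair] = s
    return edges


def _attach_annotations(
    net: EvidenceNetwork, annotations: AnnotationTable | None
) -> None:
    if annotations is None:
        return
    for pair in net.edges:
        descs = annotations.lookup(*pair)
        if descs:
            net.annotations[pair] = list(descs)


def build_evidence_network(
    graph: EvidenceGraph | WeightedView,
    drug: str,
    mediator: str,
    n_nodes: int = DEFAULT_N,
    max_intermediates: int | None = DEFAULT_MAX_INTERMEDIATES,
    weights: ChannelWeights | None = None,
    annotations: AnnotationTable | None = None,
) -> EvidenceNetwork:
    """Build the evidence network for one drug–mediator pair.

    Parameters
    ----------
    graph
        The master evidence graph (or a prepared :class:`WeightedView`).
    drug, mediator
        Node ids of the compound (source) and mediator gene (target).
    n_nodes
        Stopping threshold ``N``: accept paths until the merged network has
        at least this many distinct nodes (overshoot allowed).
    max_intermediates
        Maximum intermediate genes per accepted path (``None`` = unlimited).
    weights
        Channel multipliers used to rescore edges; default keeps the
        database's combined scores.
    annotations
        Optional edge-description table; matching descriptions are attached
        to the network's edges.

    Returns
    -------
    EvidenceNetwork
        With ``paths`` empty when no qualifying path exists (the pair being
        disconnected is a result, not an error).
    """
    view = graph if isinstance(graph, WeightedView) else WeightedView(graph, weights)
    if drug not in view.adj:
        raise KeyError(f"unknown node {drug!r}")
    if mediator not in view.adj:
        raise KeyError(f"unknown node {mediator!r}")
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    accepted: list[WeightedPath] = []
    distinct: set[str] = set()
    stop_reason = "exhausted"
    for path in iter_shortest_paths(view, drug, mediator):
        if (
            max_intermediates is not None
            and path.n_intermediates > max_intermediates
        ):
            continue
        accepted.append(path)
        distinct.update(path.nodes)
        if len(distinct) >= n_nodes:
            stop_reason = "node_threshold"
            break
    net = EvidenceNetwork(
        sources=frozenset({drug}),
        target=mediator,
        paths=accepted,
        edges=_edges_of(accepted),
        stop_reason=stop_reason,
    )
    _attach_annotations(net, annotations)
    logger.info(
        "evidence network %s→%s: %d paths, %d nodes, stop=%s",
        drug,
        mediator,
        len(accepted),
        net.n_nodes,
        stop_reason,
    )
    return net


def intermediate_count(path: WeightedPath) -> int:
    """Number of genes strictly between a path's endpoints."""
    if len(path.nodes) < 2:
        raise ValueError("path must have at least one edge")
    return len(path.nodes) - 2


def classify_pair(
    graph: EvidenceGraph,
    drug: str,
    mediator: str,
    weights: ChannelWeights | None = None,
    max_intermediates: int = DEFAULT_MAX_INTERMEDIATES,
) -> PairCategory:
    """Classify a drug–mediator pair by intermediate-gene distance.

    A pair is ``direct`` whenever the graph holds a drug–mediator edge, even
    if some multi-hop path is lighter; otherwise the weight-shortest path's
    intermediate count (1–3) is the category, and pairs that are
    disconnected or only reachable through more than ``max_intermediates``
    genes are ``unreachable``.  Missing endpoints give ``not_in_db``.
    """
    if not (graph.has_node(drug) and graph.has_node(mediator)):
        return PairCategory.NOT_IN_DB
    if graph.has_edge(drug, mediator):
        return PairCategory.DIRECT
    path = shortest_path(graph, drug, mediator, weights)
    if path is None:
        return PairCategory.UNREACHABLE
    count = intermediate_count(path)
    if count <= max_intermediates:
        return PairCategory(str(count))
    return PairCategory.UNREACHABLE


class NextShortestSession:
    """Incremental path exploration for one pair under fixed weights.

    Mirrors the portal's "Next Shortest" button: each call to
    :meth:`next_shortest` reveals one more path of the K-shortest sequence;
    ``None`` signals exhaustion.  Re-initialize with different weights to
    recompute the ordering.
    """

    def __init__(
        self,
        graph: EvidenceGraph,
        drug: str,
        mediator: str,
        weights: ChannelWeights | None = None,
        max_intermediates: int | None = None,
    ) -> None:
        self.view = WeightedView(graph, weights)
        if drug not in self.view.adj:
            raise KeyError(f"unknown node {drug!r}")
        if mediator not in self.view.adj:
            raise KeyError(f"unknown node {mediator!r}")
        self.drug = drug
        self.mediator = mediator
        self.max_intermediates = max_intermediates
        self.revealed: list[WeightedPath] = []
        self._iter: Iterator[WeightedPath] = iter_shortest_paths(
            self.view, drug, mediator
        )

    def next_shortest(self) -> WeightedPath | None:
        """The next path in (weight, lexicographic) order, or ``None``."""
        for path in self._iter:
            if (
                self.max_intermediates is not None
                and path.n_intermediates > self.max_intermediates
            ):
                continue
            self.revealed.append(path)
            return path
        return None
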