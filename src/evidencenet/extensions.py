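"""Evidence-network extensions beyond the basic drug–mediator pair.

Three variants of the core construction:

* **single-source** — start from a mediator alone and pull in its ``k``
  closest chemical nodes by shortest-path weight, useful when the original
  compound is absent from the chemical database or when candidate compounds
  for a mediator are sought (e.g. combination-therapy leads);
* **pathway-weighted** — augment a drug–mediator network with evidence
  subnetworks from the drug to each direct neighbor of the mediator in its
  differential dependency network (DDN), then induce every master-graph edge
  among the merged node set, preserving the mediator's pathway context;
* **condition-specific** — split the DDN neighbors by the condition
  (drug-sensitive vs non-sensitive cell lines) in which their dependency on
  the mediator appears, and build one pathway-weighted network per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .graph import AnnotationTable, EvidenceGraph
from .evidence_net import (
    DEFAULT_MAX_INTERMEDIATES,
    DEFAULT_N,
    EvidenceNetwork,
    _attach_annotations,
    _edges_of,
    build_evidence_network,
)
from .pathfinding import ChannelWeights, WeightedView

logger = logging.getLogger(__name__)

CONDITIONS = ("sensitive", "non_sensitive", "shared")


@dataclass
class DDNContext:
    """A mediator's direct neighbors in a differential dependency network.

    Each neighbor carries the condition of the dependency edge that links it
    to the mediator: specific to the drug-sensitive condition, specific to
    the non-sensitive condition, or shared by both.
    """

    mediator: str
    neighbors: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for node, condition in self.neighbors:
            if node == self.mediator:
                raise ValueError(
                    f"mediator {self.mediator!r} listed as its own neighbor"
                )
            if condition not in CONDITIONS:
                raise ValueError(f"unknown condition {condition!r}")

    def of_condition(self, *conditions: str) -> list[str]:
        return sorted(
            {n for n, c in self.neighbors if c in conditions}
        )

    @classmethod
    def from_tsv(cls, stream: Iterable[str], mediator: str) -> "DDNContext":
        """Load neighbors of one mediator from a (mediator, neighbor,
        condition) TSV."""
        neighbors = []
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"line {line_no}: expected 3 columns, got {len(fields)}"
                )
            med, neighbor, condition = fields
            if med == mediator:
                neighbors.append((neighbor, condition))
        return cls(mediator=mediator, neighbors=neighbors)


def single_source_network(
    graph: EvidenceGraph,
    mediator: str,
    k_drugs: int,
    n_nodes: int = DEFAULT_N,
    weights: ChannelWeights | None = None,
    max_intermediates: int | None = DEFAULT_MAX_INTERMEDIATES,
    annotations: AnnotationTable | None = None,
) -> EvidenceNetwork:
    """Evidence network from a mediator out to its k closest chemicals.

    The ``k_drugs`` chemical nodes with smallest shortest-path weight to the
    mediator are selected (distance ties broken by node id); an evidence
    network is built from each to the mediator and all are merged.
    """
    if k_drugs < 1:
        raise ValueError("k_drugs must be >= 1")
    view = WeightedView(graph, weights)
    if mediator not in view.adj:
        raise KeyError(f"unknown node {mediator!r}")
    dist = view.distances_from(mediator)
    reachable = sorted(
        (dist[c], c) for c in graph.chemical_nodes() if c in dist
    )
    selected = [c for _, c in reachable[:k_drugs]]
    if not selected:
        return EvidenceNetwork(
            sources=frozenset(), target=mediator, paths=[],
            stop_reason="no_reachable_chemical",
        )
    paths = []
    for drug in selected:
        sub = build_evidence_network(
            view, drug, mediator, n_nodes, max_intermediates, weights
        )
        paths.extend(sub.paths)
    net = EvidenceNetwork(
        sources=frozenset(selected),
        target=mediator,
        paths=paths,
        edges=_edges_of(paths),
        stop_reason="merged",
    )
    _attach_annotations(net, annotations)
    return net


def pathway_weighted_network(
    graph: EvidenceGraph,
    drug: str,
    ddn: DDNContext,
    n_nodes: int = DEFAULT_N,
    max_intermediates: int | None = DEFAULT_MAX_INTERMEDIATES,
    weights: ChannelWeights | None = None,
    annotations: AnnotationTable | None = None,
    neighbors: Iterable[str] | None = None,
) -> EvidenceNetwork:
    """Evidence network preserving the mediator's DDN pathway context.

    An evidence subnetwork is built from the drug to the mediator and from
    the drug to each DDN neighbor; the merged node set (all subnetwork nodes
    plus the mediator and every neighbor) then has every master-graph edge
    among its members induced.  Neighbors with no qualifying path — or
    absent from the graph entirely — are retained as isolated nodes.

    ``neighbors`` restricts the construction to a subset of the DDN
    neighbors (used by the condition-specific variant); default is all.
    """
    view = WeightedView(graph, weights)
    if drug not in view.adj:
        raise KeyError(f"unknown node {drug!r}")
    if ddn.mediator not in view.adj:
        raise KeyError(f"unknown node {ddn.mediator!r}")
    if neighbors is None:
        wanted = ddn.of_condition(*CONDITIONS)
    else:
        wanted = sorted(set(neighbors))
    labels = {n: c for n, c in ddn.neighbors}

    targets = [ddn.mediator] + [n for n in wanted if n != ddn.mediator]
    paths = []
    path_nodes: set[str] = set()
    for target in targets:
        if target not in view.adj:
            logger.warning(
                "DDN neighbor %r not in graph; kept as isolated node", target
            )
            continue
        sub = build_evidence_network(
            view, drug, target, n_nodes, max_intermediates, weights
        )
        paths.extend(sub.paths)
        for path in sub.paths:
            path_nodes.update(path.nodes)
    merged = path_nodes | {drug, ddn.mediator} | set(wanted)
    # Induce every master-graph edge among the merged node set.
    edges = _edges_of(paths)
    ordered = sorted(merged)
    for i, u in enumerate(ordered):
        if not graph.has_node(u):
            continue
        for v in ordered[i + 1 :]:
            if graph.has_node(v) and graph.has_edge(u, v):
                edges.setdefault((u, v), view.score(u, v))
    isolated = frozenset(merged - path_nodes - {drug, ddn.mediator})
    net = EvidenceNetwork(
        sources=frozenset({drug}),
        target=ddn.mediator,
        paths=paths,
        edges=edges,
        isolated_nodes=isolated,
        neighbor_labels={n: labels[n] for n in wanted if n in labels},
        stop_reason="merged",
    )
    _attach_annotations(net, annotations)
    return net


def condition_specific_networks(
    graph: EvidenceGraph,
    drug: str,
    ddn: DDNContext,
    n_nodes: int = DEFAULT_N,
    max_intermediates: int | None = DEFAULT_MAX_INTERMEDIATES,
    weights: ChannelWeights | None = None,
    annotations: AnnotationTable | None = None,
    specific_only: bool = False,
) -> tuple[EvidenceNetwork, EvidenceNetwork]:
    """One pathway-weighted network per condition.

    The sensitive network is built from the neighbors whose DDN dependency
    is sensitive-specific (plus shared, unless ``specific_only``); likewise
    for the non-sensitive network.  Each network's ``neighbor_labels``
    records which of its nodes are condition-specific neighbors.
    """
    shared: tuple[str, ...] = () if specific_only else ("shared",)
    sensitive = pathway_weighted_network(
        graph, drug, ddn, n_nodes, max_intermediates, weights, annotations,
        neighbors=ddn.of_condition("sensitive", *shared),
    )
    non_sensitive = pathway_weighted_network(
        graph, drug, ddn, n_nodes, max_intermediates, weights, annotations,
        neighbors=ddn.of_condition("non_sensitive", *shared),
    )
    return sensitive, non_sensitive
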