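"""Core containers for the heterogeneous chemical–protein evidence graph.

The graph mirrors how STITCH/STRING distribute their networks: undirected
edges between chemical (``CID…``) and protein (``taxon.ENSP…``) identifiers,
each edge carrying per-channel evidence sub-scores and a combined confidence
score, all in [0, 1] after scaling from the databases' integer 0–1000 grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Union vocabulary of evidence channels across the STRING protein-link and
#: STITCH chemical-link dialects.
CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
    "prediction",
    "similarity",
)

PROTEIN_CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)
CHEM_PROTEIN_CHANNELS: tuple[str, ...] = (
    "experimental",
    "prediction",
    "database",
    "textmining",
)
CHEM_CHEM_CHANNELS: tuple[str, ...] = (
    "similarity",
    "experimental",
    "prediction",
    "database",
    "textmining",
)


class GraphError(ValueError):
    """Raised for malformed identifiers, scores or graph operations."""


def node_kind(raw: str) -> str:
    """Classify a node identifier as ``"chemical"`` or ``"protein"``.

    Chemical identifiers start with ``CID`` (PubChem compound ids in the
    STITCH convention); everything else is treated as a protein.
    """
    if not raw:
        raise GraphError("empty node identifier")
    return "chemical" if raw.startswith("CID") else "protein"


def normalize_chemical_id(raw: str) -> str:
    """Map a stereospecific ``CIDs…`` id to its merged ``CIDm…`` form.

    STITCH issues both stereospecific (``CIDs``) and merged (``CIDm``)
    compound identifiers; stereoisomers and salt forms are treated as one
    compound, so everything is folded onto the merged id.
    """
    if raw.startswith("CIDs"):
        return "CIDm" + raw[4:]
    return raw


def _canon_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EvidenceEdge:
    """One undirected association with per-channel evidence scores.

    ``channel_scores`` holds only the channels with a reported sub-score;
    ``reported_combined`` is the database's aggregate confidence.
    """

    u: str
    v: str
    channel_scores: Mapping[str, float]
    reported_combined: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise GraphError(f"self-loop on {self.u!r}")
        for name, s in self.channel_scores.items():
            if name not in CHANNELS:
                raise GraphError(f"unknown evidence channel {name!r}")
            if not 0.0 <= s <= 1.0:
                raise GraphError(f"channel {name} score {s} outside [0, 1]")
        if not 0.0 <= self.reported_combined <= 1.0:
            raise GraphError(
                f"combined score {self.reported_combined} outside [0, 1]"
            )

    @property
    def pair(self) -> tuple[str, str]:
        """Order-normalized endpoint pair."""
        return _canon_pair(self.u, self.v)


class EvidenceGraph:
    """Undirected heterogeneous graph of chemical and protein nodes.

    Thin wrapper over :class:`networkx.Graph` that enforces the evidence-graph
    invariants (no self-loops, scores in [0, 1], undirected deduplication) and
    carries an alias map from external identifiers (InChIKeys, names) to node
    ids.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        self.aliases: dict[str, str] = {}

    # -- nodes ------------------------------------------------------------

    def add_node(self, raw: str) -> None:
        self._g.add_node(raw, kind=node_kind(raw))

    def has_node(self, raw: str) -> bool:
        return self._g.has_node(raw)

    def kind(self, raw: str) -> str:
        return self._g.nodes[raw]["kind"]

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def chemical_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d["kind"] == "chemical"
        )

    def protein_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d["kind"] == "protein"
        )

    # -- edges ------------------------------------------------------------

    def add_edge(
        self,
        edge: EvidenceEdge,
        on_collision: str = "max",
    ) -> None:
        """Insert an edge; ``on_collision`` is ``"max"`` (channel-wise
        maximum merge), ``"error"`` (raise unless scores identical), or
        ``"identical"`` (raise on any conflict, silently accept duplicates).
        """
        u, v = edge.pair
        self.add_node(u)
        self.add_node(v)
        existing = self._g.get_edge_data(u, v)
        if existing is None:
            self._g.add_edge(
                u,
                v,
                channels=dict(edge.channel_scores),
                combined=edge.reported_combined,
            )
            return
        same = (
            existing["channels"] == dict(edge.channel_scores)
            and existing["combined"] == edge.reported_combined
        )
        if same:
            return
        if on_collision in ("error", "identical"):
            raise GraphError(
                f"conflicting duplicate edge {u}–{v}: "
                f"{existing['channels']}/{existing['combined']} vs "
                f"{dict(edge.channel_scores)}/{edge.reported_combined}"
            )
        merged = dict(existing["channels"])
        for name, s in edge.channel_scores.items():
            merged[name] = max(merged.get(name, 0.0), s)
        self._g.add_edge(
            u,
            v,
            channels=merged,
            combined=max(existing["combined"], edge.reported_combined),
        )

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def get_edge(self, u: str, v: str) -> EvidenceEdge:
        data = self._g.get_edge_data(u, v)
        if data is None:
            raise KeyError(f"no edge {u}–{v}")
        cu, cv = _canon_pair(u, v)
        return EvidenceEdge(cu, cv, dict(data["channels"]), data["combined"])

    @property
    def edges(self) -> list[EvidenceEdge]:
        out = [
            EvidenceEdge(
                *_canon_pair(u, v), dict(d["channels"]), d["combined"]
            )
            for u, v, d in self._g.edges(data=True)
        ]
        return sorted(out, key=lambda e: e.pair)

    def neighbors(self, raw: str) -> list[str]:
        if not self._g.has_node(raw):
            raise KeyError(f"unknown node {raw!r}")
        return sorted(self._g.neighbors(raw))

    def degree(self, raw: str) -> int:
        return self._g.degree(raw)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # -- aliases ----------------------------------------------------------

    def add_alias(self, alias: str, node: str) -> None:
        self.aliases[alias] = node

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceGraph):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if self.aliases != other.aliases:
            return False
        mine = {e.pair: (dict(e.channel_scores), e.reported_combined) for e in self.edges}
        theirs = {
            e.pair: (dict(e.channel_scores), e.reported_combined)
            for e in other.edges
        }
        return mine == theirs

    def __repr__(self) -> str:
        return (
            f"EvidenceGraph({self.n_nodes} nodes, {self.n_edges} edges, "
            f"{len(self.aliases)} aliases)"
        )


@dataclass
class AnnotationTable:
    """Free-text evidence descriptions keyed by order-normalized node pair."""

    entries: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def add(self, u: str, v: str, description: str) -> None:
        self.entries.setdefault(_canon_pair(u, v), []).append(description)

    def lookup(self, u: str, v: str) -> list[str]:
        """Descriptions for a pair; missing pairs yield an empty list."""
        return self.entries.get(_canon_pair(u, v), [])

    def __len__(self) -> int:
        return len(self.entries)
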