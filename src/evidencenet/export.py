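"""Serialization of evidence networks for interactive viewers.

Two formats: a Cytoscape.js-style elements document (JSON) for web viewers,
with edge opacity mapped to the effective evidence score, per-edge evidence
summaries and outbound links into the public chemical/protein databases;
and standard GraphML for desktop graph tools.  Both emitters sort their
elements, so identical inputs give byte-identical output.
"""

from __future__ import annotations

import json
from typing import Literal, Mapping

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evidence_net import EvidenceNetwork
from .graph import AnnotationTable, node_kind

FORMAT_VERSION = "1.0"
OPACITY_FLOOR = 0.1

#: Default outbound-link templates, keyed by whether a chemical is involved.
LINK_TEMPLATES = {
    "protein": "https://string-db.org/cgi/network?identifiers={u}%0d{v}",
    "chemical": "http://stitch.embl.de/cgi/network?identifiers={u}%0d{v}",
}

NodeRole = Literal[
    "source",
    "target",
    "intermediate",
    "isolated",
    "neighbor-sensitive",
    "neighbor-non-sensitive",
]


class NodeData(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    kind: Literal["chemical", "protein"]
    label: str
    role: NodeRole


class EdgeData(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    source: str
    target: str
    score: float = Field(ge=0.0, le=1.0)
    opacity: float = Field(ge=OPACITY_FLOOR, le=1.0)
    evidence: str
    link: str


class NodeElement(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data: NodeData


class EdgeElement(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data: EdgeData


class Elements(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nodes: list[NodeElement]
    edges: list[EdgeElement]


class ViewerDocument(BaseModel):
    """Validated viewer graph document (Cytoscape.js elements shape)."""

    model_config = ConfigDict(extra="forbid")

    format_version: str
    elements: Elements

    @model_validator(mode="after")
    def _edges_reference_nodes(self) -> "ViewerDocument":
        ids = {n.data.id for n in self.elements.nodes}
        for e in self.elements.edges:
            if e.data.source not in ids or e.data.target not in ids:
                raise ValueError(
                    f"edge {e.data.id} references a missing node"
                )
        return self


def _node_role(net: EvidenceNetwork, node: str) -> str:
    if node in net.sources:
        return "source"
    if node == net.target:
        return "target"
    label = net.neighbor_labels.get(node)
    if label == "sensitive":
        return "neighbor-sensitive"
    if label == "non_sensitive":
        return "neighbor-non-sensitive"
    if node in net.isolated_nodes:
        return "isolated"
    return "intermediate"


def _opacity(score: float) -> float:
    return min(max(score, OPACITY_FLOOR), 1.0)


def _link(u: str, v: str, templates: Mapping[str, str]) -> str:
    key = (
        "chemical"
        if "chemical" in (node_kind(u), node_kind(v))
        else "protein"
    )
    return templates[key].format(u=u, v=v)


def build_viewer_document(
    net: EvidenceNetwork,
    annotations: AnnotationTable | None = None,
    labels: Mapping[str, str] | None = None,
    link_templates: Mapping[str, str] | None = None,
) -> ViewerDocument:
    """Assemble and validate the viewer document for a network."""
    labels = labels or {}
    templates = link_templates or LINK_TEMPLATES
    nodes = [
        NodeElement(
            data=NodeData(
                id=node,
                kind=node_kind(node),
                label=labels.get(node, node),
                role=_node_role(net, node),
            )
        )
        for node in sorted(net.nodes)
    ]
    edges = []
    for (u, v), score in sorted(net.edges.items()):
        descs = list(net.annotations.get((u, v), []))
        if annotations is not None and not descs:
            descs = annotations.lookup(u, v)
        edges.append(
            EdgeElement(
                data=EdgeData(
                    id=f"{u}|{v}",
                    source=u,
                    target=v,
                    score=score,
                    opacity=_opacity(score),
                    evidence="; ".join(descs),
                    link=_link(u, v, templates),
                )
            )
        )
    return ViewerDocument(
        format_version=FORMAT_VERSION,
        elements=Elements(nodes=nodes, edges=edges),
    )


def to_viewer_json(
    net: EvidenceNetwork,
    annotations: AnnotationTable | None = None,
    labels: Mapping[str, str] | None = None,
    link_templates: Mapping[str, str] | None = None,
) -> str:
    """Deterministic viewer JSON text for a network."""
    doc = build_viewer_document(net, annotations, labels, link_templates)
    return json.dumps(doc.model_dump(), indent=1, sort_keys=True) + "\n"


def viewer_json_schema() -> dict:
    """JSON Schema of the viewer document (for external consumers)."""
    return ViewerDocument.model_json_schema()


def to_networkx(net: EvidenceNetwork) -> nx.Graph:
    """The network as a :class:`networkx.Graph` with role/score attributes."""
    g = nx.Graph()
    for node in sorted(net.nodes):
        g.add_node(node, kind=node_kind(node), role=_node_role(net, node))
    for (u, v), score in sorted(net.edges.items()):
        g.add_edge(u, v, score=score, opacity=_opacity(score))
    return g


def to_graphml(net: EvidenceNetwork) -> str:
    """Deterministic GraphML text with kind/role/score attributes."""
    g = to_networkx(net)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
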