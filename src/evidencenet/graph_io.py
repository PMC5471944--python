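"""Parsers and writers for STITCH/STRING-dialect flat files.

STRING distributes protein–protein links as whitespace-delimited flat files
with one header line, integer channel scores on a 0–1000 grid, and every
undirected pair listed in both orders.  STITCH uses the same layout for
chemical–protein and chemical–chemical links.  This module reconstructs those
files into a single :class:`~evidencenet.graph.EvidenceGraph`, writes graphs
back out in the same dialects, and loads the delimited edge-annotation table
used to describe evidence on exported networks.

Column identities are taken from the header by name, never by position.
Internally every score is the file integer divided by 1000, so all scores
live in [0, 1].
"""

from __future__ import annotations

import json
import logging
from typing import IO, Iterable

from .graph import (
    CHANNELS,
    CHEM_CHEM_CHANNELS,
    CHEM_PROTEIN_CHANNELS,
    PROTEIN_CHANNELS,
    AnnotationTable,
    EvidenceEdge,
    EvidenceGraph,
    GraphError,
    node_kind,
    normalize_chemical_id,
)

logger = logging.getLogger(__name__)

GRAPH_STORE_VERSION = 1


class ParseError(ValueError):
    """Malformed flat-file input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None) -> None:
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _parse_header(
    line: str, expected_id_cols: int = 2
) -> tuple[list[str], str]:
    cols = line.split()
    if len(cols) < expected_id_cols + 1:
        raise ParseError(f"header has too few columns: {line!r}", 1)
    if cols[-1] != "combined_score":
        raise ParseError(
            f"last header column must be 'combined_score', got {cols[-1]!r}", 1
        )
    channel_cols = cols[expected_id_cols:-1]
    for name in channel_cols:
        if name not in CHANNELS:
            raise ParseError(f"unknown score column {name!r}", 1)
    return channel_cols, cols[-1]


def _parse_score(token: str, line_no: int) -> float:
    try:
        value = int(token)
    except ValueError:
        raise ParseError(f"non-integer score {token!r}", line_no) from None
    if not 0 <= value <= 1000:
        raise ParseError(f"score {value} outside [0, 1000]", line_no)
    return value / 1000.0


def _parse_links(
    stream: Iterable[str],
    *,
    chemical_cols: tuple[bool, bool],
    on_collision: str,
    want_channels: bool | None = None,
) -> EvidenceGraph:
    graph = EvidenceGraph()
    lines = iter(stream)
    try:
        header = next(lines)
    except StopIteration:
        raise ParseError("empty stream: missing header") from None
    channel_cols, _ = _parse_header(header)
    if want_channels is True and not channel_cols:
        raise ParseError("detailed dialect requires channel score columns", 1)
    if want_channels is False and channel_cols:
        raise ParseError(
            "combined-only dialect must not carry channel columns", 1
        )
    ncols = 2 + len(channel_cols) + 1
    for line_no, line in enumerate(lines, start=2):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != ncols:
            raise ParseError(
                f"expected {ncols} columns, got {len(tokens)}", line_no
            )
        u, v = tokens[0], tokens[1]
        if chemical_cols[0]:
            u = normalize_chemical_id(u)
        if chemical_cols[1]:
            v = normalize_chemical_id(v)
        for raw, want_chem in ((u, chemical_cols[0]), (v, chemical_cols[1])):
            is_chem = node_kind(raw) == "chemical"
            if is_chem != want_chem:
                raise ParseError(
                    f"identifier {raw!r} is not a "
                    f"{'chemical' if want_chem else 'protein'} id",
                    line_no,
                )
        if u == v:
            logger.warning("line %d: dropping self-loop on %r", line_no, u)
            continue
        scores = {
            name: _parse_score(tok, line_no)
            for name, tok in zip(channel_cols, tokens[2:-1])
        }
        combined = _parse_score(tokens[-1], line_no)
        channel_scores = {k: s for k, s in scores.items() if s > 0.0}
        edge = EvidenceEdge(u, v, channel_scores, combined)
        try:
            graph.add_edge(edge, on_collision=on_collision)
        except GraphError as exc:
            raise ParseError(str(exc), line_no) from exc
    return graph


def parse_protein_links(
    stream: Iterable[str], dialect: str = "detailed"
) -> EvidenceGraph:
    """Parse a STRING ``protein.links.detailed`` (or ``combined-only``) file.

    Both orders of each pair collapse to one undirected edge; a pair that
    reappears with *conflicting* scores raises :class:`ParseError`.

    Parameters
    ----------
    stream
        Iterable of lines; the first line is the header.
    dialect
        ``"detailed"`` (seven channel columns) or ``"combined-only"``
        (three columns: two ids and ``combined_score``).
    """
    if dialect not in ("detailed", "combined-only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return _parse_links(
        stream,
        chemical_cols=(False, False),
        on_collision="error",
        want_channels=dialect == "detailed",
    )


def parse_chemical_links(
    stream: Iterable[str], kind: str = "chemical-protein"
) -> EvidenceGraph:
    """Parse a STITCH chemical-links file into a partial evidence graph.

    Stereospecific ``CIDs…`` identifiers are folded onto their merged
    ``CIDm…`` form at parse time, so all salt and stereo forms of a compound
    become one node; score collisions arising from that merge (or from
    duplicate rows) resolve by per-channel maximum.

    Parameters
    ----------
    stream
        Iterable of lines; the first line is the header.
    kind
        ``"chemical-protein"`` or ``"chemical-chemical"``.
    """
    if kind == "chemical-protein":
        chemical_cols = (True, False)
    elif kind == "chemical-chemical":
        chemical_cols = (True, True)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return _parse_links(stream, chemical_cols=chemical_cols, on_collision="max")


def merge_graphs(parts: Iterable[EvidenceGraph]) -> EvidenceGraph:
    """Union partial graphs into one evidence graph.

    Node sets, edge sets and alias maps are unioned; when the same edge
    appears in several parts its channel scores merge by element-wise maximum
    and the combined score by maximum, so the merge is commutative,
    associative and idempotent.
    """
    out = EvidenceGraph()
    for part in parts:
        for node in part.nodes:
            out.add_node(node)
        for edge in part.edges:
            out.add_edge(edge, on_collision="max")
        out.aliases.update(part.aliases)
    return out


def _format_score(s: float) -> str:
    return str(round(s * 1000))


def write_flat_files(graph: EvidenceGraph) -> dict[str, str]:
    """Serialize a graph back to flat-file text, one section per dialect.

    Returns a mapping with keys ``protein_links``, ``chemical_protein_links``,
    ``chemical_chemical_links`` and ``nodes`` (the link dialects carry only
    edges, so the node list is what preserves isolated nodes); parsing the
    output reproduces the graph (scores re-quantized to the 1/1000 grid).
    Each undirected pair is written once, endpoints in sorted order.
    """
    sections = {
        "nodes": ["node_id"] + graph.nodes,
        "protein_links": [
            "protein1 protein2 " + " ".join(PROTEIN_CHANNELS) + " combined_score"
        ],
        "chemical_protein_links": [
            "chemical protein "
            + " ".join(CHEM_PROTEIN_CHANNELS)
            + " combined_score"
        ],
        "chemical_chemical_links": [
            "chemical1 chemical2 "
            + " ".join(CHEM_CHEM_CHANNELS)
            + " combined_score"
        ],
    }
    for edge in graph.edges:
        u, v = edge.pair
        ku, kv = node_kind(u), node_kind(v)
        if ku == "protein" and kv == "protein":
            key, channels = "protein_links", PROTEIN_CHANNELS
            first, second = u, v
        elif ku == "chemical" and kv == "chemical":
            key, channels = "chemical_chemical_links", CHEM_CHEM_CHANNELS
            first, second = u, v
        else:
            key, channels = "chemical_protein_links", CHEM_PROTEIN_CHANNELS
            first, second = (u, v) if ku == "chemical" else (v, u)
        unknown = set(edge.channel_scores) - set(channels)
        if unknown:
            raise GraphError(
                f"edge {u}–{v} carries channels {sorted(unknown)} not "
                f"representable in the {key} dialect"
            )
        row = [first, second]
        row += [
            _format_score(edge.channel_scores.get(c, 0.0)) for c in channels
        ]
        row.append(_format_score(edge.reported_combined))
        sections[key].append(" ".join(row))
    return {k: "\n".join(v) + "\n" for k, v in sections.items()}


def parse_node_list(stream: Iterable[str]) -> EvidenceGraph:
    """Parse a ``nodes`` section (header + one node id per line)."""
    graph = EvidenceGraph()
    lines = iter(stream)
    try:
        header = next(lines)
    except StopIteration:
        raise ParseError("empty stream: missing header") from None
    if header.split() != ["node_id"]:
        raise ParseError(f"unexpected node-list header {header!r}", 1)
    for line in lines:
        raw = line.strip()
        if raw:
            graph.add_node(normalize_chemical_id(raw))
    return graph


def load_annotations(stream: Iterable[str], sep: str = "\t") -> AnnotationTable:
    """Load a three-column (node id, node id, description) annotation table.

    Keys are order-normalized; multiple rows for the same pair accumulate.
    """
    table = AnnotationTable()
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != 3:
            raise ParseError(
                f"expected 3 columns, got {len(fields)}", line_no
            )
        table.add(fields[0], fields[1], fields[2])
    return table


def load_aliases(stream: Iterable[str], graph: EvidenceGraph) -> None:
    """Load a TSV alias table (node_id, alias_type, alias_value) into a graph.

    Alias types are free-form (``inchikey``, ``name``, ``cid``); InChIKey
    aliases are what :func:`evidencenet.chem_id.match_chemical` consumes.
    """
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"expected 3 columns, got {len(fields)}", line_no)
        node_id, alias_type, alias_value = fields
        graph.add_alias(alias_value, normalize_chemical_id(node_id))


# -- portable graph store -------------------------------------------------


def save_graph(graph: EvidenceGraph, fh: IO[str]) -> None:
    """Write the versioned JSON graph store (portable across CLI runs)."""
    doc = {
        "format": "evidencenet-graph",
        "version": GRAPH_STORE_VERSION,
        "nodes": graph.nodes,
        "edges": [
            {
                "u": e.u,
                "v": e.v,
                "channels": dict(sorted(e.channel_scores.items())),
                "combined": e.reported_combined,
            }
            for e in graph.edges
        ],
        "aliases": dict(sorted(graph.aliases.items())),
    }
    json.dump(doc, fh, indent=1, sort_keys=True)
    fh.write("\n")


def load_graph(fh: IO[str]) -> EvidenceGraph:
    """Read a graph store written by :func:`save_graph`."""
    doc = json.load(fh)
    if doc.get("format") != "evidencenet-graph":
        raise ParseError("not an evidencenet graph store")
    if doc.get("version") != GRAPH_STORE_VERSION:
        raise ParseError(
            f"unsupported graph store version {doc.get('version')!r}"
        )
    graph = EvidenceGraph()
    for node in doc["nodes"]:
        graph.add_node(node)
    for rec in doc["edges"]:
        graph.add_edge(
            EvidenceEdge(rec["u"], rec["v"], rec["channels"], rec["combined"]),
            on_collision="error",
        )
    graph.aliases.update(doc.get("aliases", {}))
    return graph
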