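"""Edge weighting and exact shortest / K-shortest loopless path search.

Evidence edges are turned into weights by ``w = 1 − S``: an edge's evidence
score ``S`` in [0, 1] becomes a nonnegative cost, so well-evidenced
associations are preferred by shortest-path search.  ``S`` is either the
database's combined score (when all channel multipliers are at their default
of 1.0) or a noisy-OR recombination of the per-channel sub-scores scaled by
user-chosen multipliers, which lets a user down-weight or silence whole
evidence channels (e.g. text mining) and have every path recomputed.

Path search is exact and deterministic: among minimal-weight loopless paths
the lexicographically smallest node-id sequence wins.  The K-shortest
enumeration is Yen's algorithm over a best-first single-pair solver; see
``docs/methods.md`` for the tie-break and pruning semantics.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Mapping

from .graph import EvidenceEdge, EvidenceGraph, GraphError

#: Named channel-multiplier presets mirroring the portal's weight menu.
PRESETS: dict[str, float] = {"NONE": 0.0, "LOW": 0.5, "DEFAULT": 1.0}


@dataclass(frozen=True)
class ChannelWeights:
    """Per-channel multipliers in [0, 1]; unspecified channels default to 1.

    ``ChannelWeights()`` (all defaults) preserves the database's combined
    scores exactly; anything else switches effective scoring to the noisy-OR
    recombination of sub-scores.
    """

    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.multipliers.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"multiplier {name}={m} outside [0, 1]")

    def multiplier(self, channel: str) -> float:
        return self.multipliers.get(channel, 1.0)

    @property
    def is_default(self) -> bool:
        return all(m == 1.0 for m in self.multipliers.values())

    @classmethod
    def from_specs(cls, specs: Mapping[str, str | float]) -> "ChannelWeights":
        """Build from CLI-style specs (``{"textmining": "NONE"}`` or numbers)."""
        multipliers = {}
        for name, value in specs.items():
            if isinstance(value, str):
                token = value.upper()
                if token in PRESETS:
                    value = PRESETS[token]
                else:
                    value = float(value)
            multipliers[name] = float(value)
        return cls(multipliers)


@dataclass(frozen=True)
class WeightedPath:
    """A loopless path with its total weight and per-edge effective scores."""

    nodes: tuple[str, ...]
    total_weight: float
    edge_scores: tuple[float, ...]

    @property
    def n_intermediates(self) -> int:
        return max(len(self.nodes) - 2, 0)

    def __len__(self) -> int:
        return len(self.nodes)


def effective_score(edge: EvidenceEdge, weights: ChannelWeights) -> float:
    """Effective evidence score ``S`` of an edge under channel multipliers.

    With all multipliers at 1.0 the database's ``reported_combined`` is
    passed through unchanged (it includes the databases' own prior
    correction, which cannot be reproduced from the sub-scores).  Otherwise
    ``S = 1 − Π_c (1 − m_c · s_c)`` over the channels present on the edge.
    """
    if weights.is_default:
        return edge.reported_combined
    complement = 1.0
    for channel, s in edge.channel_scores.items():
        complement *= 1.0 - weights.multiplier(channel) * s
    return 1.0 - complement


def edge_weight(score: float) -> float:
    """Path-search cost of an evidence score: ``w = 1 − S``."""
    if not 0.0 <= score <= 1.0:
        raise GraphError(f"score {score} outside [0, 1]")
    return 1.0 - score


class WeightedView:
    """An evidence graph with effective scores and weights materialized.

    Precomputes, for a fixed :class:`ChannelWeights`, each edge's effective
    score and weight plus a sorted adjacency structure, so repeated path
    queries (Yen makes many) do not rescore edges.

    Weights are carried exactly: every IEEE edge weight is a binary rational,
    so all weights are rescaled onto a common power-of-two grid and summed as
    Python integers.  Path weights are then associative and comparisons
    exact, so the (weight, lexicographic) ordering of paths never depends on
    the order edges happen to be summed in.  Reported totals are the float
    rounding of the exact sum.
    """

    def __init__(self, graph: EvidenceGraph, weights: ChannelWeights | None = None):
        self.graph = graph
        self.weights = weights or ChannelWeights()
        self.scores: dict[tuple[str, str], float] = {}
        raw: dict[tuple[str, str], Fraction] = {}
        shift = 0
        for edge in graph.edges:
            s = effective_score(edge, self.weights)
            self.scores[edge.pair] = s
            f = Fraction(edge_weight(s))
            raw[edge.pair] = f
            shift = max(shift, f.denominator.bit_length() - 1)
        self._shift = shift  # all weights are multiples of 2**-shift
        self._wexact: dict[tuple[str, str], int] = {}
        adj: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
        for edge in graph.edges:
            f = raw[edge.pair]
            w = f.numerator << (shift - (f.denominator.bit_length() - 1))
            self._wexact[edge.pair] = w
            adj[edge.u].append((edge.v, w))
            adj[edge.v].append((edge.u, w))
        self.adj = {n: sorted(nbrs) for n, nbrs in adj.items()}

    def score(self, u: str, v: str) -> float:
        return self.scores[(u, v) if u <= v else (v, u)]

    def weight(self, u: str, v: str) -> int:
        """Exact edge weight, in units of ``2**-shift``."""
        return self._wexact[(u, v) if u <= v else (v, u)]

    def exact_weight(self, nodes: tuple[str, ...]) -> int:
        return sum(self.weight(a, b) for a, b in zip(nodes, nodes[1:]))

    def to_float(self, exact: int) -> float:
        return exact / (1 << self._shift) if self._shift else float(exact)

    def path(self, nodes: tuple[str, ...]) -> WeightedPath:
        """Materialize a node sequence as a :class:`WeightedPath`."""
        scores = tuple(self.score(a, b) for a, b in zip(nodes, nodes[1:]))
        return WeightedPath(
            tuple(nodes), self.to_float(self.exact_weight(nodes)), scores
        )

    def distances_from(self, source: str) -> dict[str, int]:
        """Finalized Dijkstra distances (exact units) from ``source``."""
        if source not in self.adj:
            raise KeyError(f"unknown node {source!r}")
        dist: dict[str, int] = {}
        heap: list[tuple[int, str]] = [(0, source)]
        while heap:
            d, node = heapq.heappop(heap)
            if node in dist:
                continue
            dist[node] = d
            for nbr, w in self.adj[node]:
                if nbr not in dist:
                    heapq.heappush(heap, (d + w, nbr))
        return dist


def _best_path(
    view: WeightedView,
    src: str,
    dst: str,
    *,
    forbidden_nodes: frozenset[str] = frozenset(),
    forbidden_edges: frozenset[tuple[str, str]] = frozenset(),
    heuristic: Mapping[str, int] | None = None,
) -> tuple[str, ...] | None:
    """Minimal-(weight, lexicographic) loopless path from src to dst.

    Best-first search whose priority is ``(g + h, path)``: the first goal pop
    is the minimum-weight path, and among equal-weight paths the
    lexicographically smallest node sequence.  ``heuristic`` is an admissible
    lower bound on remaining distance (distances in the unrestricted graph);
    restrictions only lengthen paths, so admissibility is preserved.
    """
    if src in forbidden_nodes or dst in forbidden_nodes:
        return None
    h = heuristic or {}
    if heuristic is not None and src not in h:
        return None  # dst unreachable even without restrictions
    start: tuple[str, ...] = (src,)
    heap: list[tuple[int, tuple[str, ...], int]] = [(h.get(src, 0), start, 0)]
    while heap:
        f, path, g = heapq.heappop(heap)
        node = path[-1]
        if node == dst:
            return path
        in_path = set(path)
        for nbr, w in view.adj[node]:
            if nbr in in_path or nbr in forbidden_nodes:
                continue
            pair = (node, nbr) if node <= nbr else (nbr, node)
            if pair in forbidden_edges:
                continue
            if heuristic is not None and nbr not in h:
                continue  # cannot reach dst from nbr at all
            g2 = g + w
            heapq.heappush(heap, (g2 + h.get(nbr, 0), path + (nbr,), g2))
    return None


def shortest_path(
    graph: EvidenceGraph | WeightedView,
    src: str,
    dst: str,
    weights: ChannelWeights | None = None,
) -> WeightedPath | None:
    """Weight-shortest loopless path, or ``None`` if disconnected.

    Ties in total weight resolve to the lexicographically smallest node-id
    sequence.  ``src == dst`` yields the trivial single-node path of weight 0.
    """
    view = graph if isinstance(graph, WeightedView) else WeightedView(graph, weights)
    if src not in view.adj:
        raise KeyError(f"unknown node {src!r}")
    if dst not in view.adj:
        raise KeyError(f"unknown node {dst!r}")
    if src == dst:
        return WeightedPath((src,), 0.0, ())
    h = view.distances_from(dst)
    nodes = _best_path(view, src, dst, heuristic=h)
    if nodes is None:
        return None
    return view.path(nodes)


def iter_shortest_paths(
    graph: EvidenceGraph | WeightedView,
    src: str,
    dst: str,
    weights: ChannelWeights | None = None,
) -> Iterator[WeightedPath]:
    """Yield all loopless src→dst paths in (weight, lexicographic) order.

    Yen's K-shortest-paths enumeration run lazily: each accepted path spawns
    spur searches rooted along it, candidates are deduplicated and popped in
    ``(weight, node-sequence)`` order, so the stream is exactly the sorted
    enumeration of all simple paths.
    """
    view = graph if isinstance(graph, WeightedView) else WeightedView(graph, weights)
    if src not in view.adj:
        raise KeyError(f"unknown node {src!r}")
    if dst not in view.adj:
        raise KeyError(f"unknown node {dst!r}")
    if src == dst:
        yield WeightedPath((src,), 0.0, ())
        return
    h = view.distances_from(dst)
    first = _best_path(view, src, dst, heuristic=h)
    if first is None:
        return
    # Deviating edges of accepted paths, indexed by shared root prefix, so
    # each spur search collects its blocked edges in O(1).
    blocked_at: dict[tuple[str, ...], set[tuple[str, str]]] = {}

    def register(path: tuple[str, ...]) -> None:
        for i in range(len(path) - 1):
            a, b = path[i], path[i + 1]
            blocked_at.setdefault(path[: i + 1], set()).add(
                (a, b) if a <= b else (b, a)
            )

    seen: set[tuple[str, ...]] = {first}
    # Heap entries carry the deviation index (Lawler's optimization): spur
    # searches below that index were already performed by the candidate's
    # ancestors, and the next alternative at each root is regenerated by
    # whichever accepted path deviated there.
    candidates: list[tuple[int, tuple[str, ...], int]] = [
        (view.exact_weight(first), first, 0)
    ]
    while candidates:
        _, path, dev = heapq.heappop(candidates)
        register(path)
        yield view.path(path)
        for i in range(dev, len(path) - 1):
            root = path[: i + 1]
            blocked = blocked_at.get(root)
            spur = _best_path(
                view,
                path[i],
                dst,
                forbidden_nodes=frozenset(root[:-1]),
                forbidden_edges=frozenset(blocked) if blocked else frozenset(),
                heuristic=h,
            )
            if spur is None:
                continue
            total = root[:-1] + spur
            if total not in seen:
                seen.add(total)
                heapq.heappush(
                    candidates, (view.exact_weight(total), total, i)
                )


def k_shortest_paths(
    graph: EvidenceGraph | WeightedView,
    src: str,
    dst: str,
    k: int,
    weights: ChannelWeights | None = None,
    max_intermediates: int | None = None,
) -> list[WeightedPath]:
    """The k best loopless paths, optionally capped in intermediate count.

    Paths whose number of intermediate nodes exceeds ``max_intermediates``
    are excluded during enumeration, so ``k`` counts accepted paths.  Fewer
    than ``k`` paths are returned when the supply is exhausted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[WeightedPath] = []
    for path in iter_shortest_paths(graph, src, dst, weights):
        if (
            max_intermediates is not None
            and path.n_intermediates > max_intermediates
        ):
            continue
        out.append(path)
        if len(out) == k:
            break
    return out
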