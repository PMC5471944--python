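# Methods

## Problem and model

Statistical screens that relate drug response to gene-network rewiring (for
example, differential-dependency analysis of drug-sensitive versus
non-sensitive cancer cell lines) produce large tables of drug–"mediator"
gene pairs with no mechanistic context. This package contextualizes such a
pair against a chemical–protein knowledge graph in the STITCH/STRING style:
an undirected graph whose edges carry a combined confidence score plus
per-channel sub-scores (experimental, database, text mining, coexpression,
…), all scaled from the databases' integer 0–1000 grid to [0, 1].

Every edge is costed as

    w_edge = 1 − S_edge

where `S_edge` is the edge's effective evidence score, so minimum-weight
paths are maximum-evidence chains of associations. An **evidence network**
for a pair (drug *D*, mediator *M*) is built by enumerating loopless paths
from *D* to *M* in nondecreasing weight (Yen's K-shortest paths) and merging
them into a sub-network until either the path supply is exhausted or the
merged sub-network contains at least *N* distinct nodes. *N* is a stopping
condition, not a floor: the final accepted path may push the node count past
*N*. Paths with more than `max_intermediates` interior genes are never
accepted — long chains of intermediaries connect almost anything to almost
anything and carry no interpretive value.

## Effective scores and channel weighting

Users can down-weight whole evidence channels (e.g. distrust text mining).
Each channel gets a multiplier `m_c ∈ [0, 1]` (presets NONE = 0, LOW = 0.5,
DEFAULT = 1; the numeric values of NONE/LOW are this package's convention).

* With **all multipliers at 1** the effective score is the file's
  `combined_score`, passed through unchanged. The public databases apply a
  prior correction when combining sub-scores that cannot be reproduced from
  the sub-scores alone, so preserving their number exactly is the only
  faithful default.
* With **any non-default multiplier** the effective score is the noisy-OR
  recombination `S = 1 − Π_c (1 − m_c·s_c)` over the channels present on
  the edge.

This creates a deliberate discontinuity at the all-default point: the
noisy-OR value at `m = 1` need not equal the reported combined score.
Monotonicity of `S` in each multiplier therefore holds *within* the
noisy-OR branch, which is what the tests assert. Silencing a channel
(`m_c = 0`) is provably identical to deleting that channel from every edge.

## Path search: exactness and determinism

Contract: among minimal-weight loopless paths, the lexicographically
smallest node-id sequence wins, and the K-shortest enumeration emits
*exactly* the sorted-by-(weight, sequence) list of all simple paths.
Three implementation choices make this exact rather than approximate:

1. **Integer weight arithmetic.** IEEE doubles are binary rationals, so all
   edge weights of a view are rescaled onto a common power-of-two grid and
   summed as Python integers. Path weights are then associative and
   comparisons exact; float addition is not associative, and last-ulp noise
   would otherwise order mathematically tied paths by summation accident
   rather than by the lexicographic rule. Reported totals are the float
   rounding of the exact sum.
2. **Best-first single-pair search** with priority `(g + h, node sequence)`
   and no node finalization, where `h` is the exact Dijkstra distance to the
   target in the unrestricted graph (admissible under any edge/node
   removals, since removals only lengthen paths). The first goal pop is the
   minimum-weight path and, among ties, the lexicographically smallest.
   Plain finalized Dijkstra does not guarantee the lexicographic part: the
   lexicographically best route to the target may pass through a node whose
   own lexicographically best shortest prefix blocks the needed tail.
   The search is worst-case exponential but exact; at the package's intended
   scale (interactive queries on sparse sub-neighborhoods, and the fixture
   sizes below) it is fast, and the admissible heuristic prunes most of the
   frontier. Finalized Dijkstra *is* used where only distances matter
   (heuristic tables, closest-chemical ranking).
3. **Yen's algorithm with Lawler's optimization.** Spur searches run only
   from a candidate's deviation index onward; deviating edges of accepted
   paths are indexed by root prefix so each spur search assembles its
   blocked-edge set in O(1). Candidates are deduplicated and popped in
   exact (weight, sequence) order. Run to exhaustion, the stream equals the
   brute-force enumeration of all simple paths — the test suite verifies
   this on hundreds of random graphs against `networkx.all_simple_paths`.

`max_intermediates` is enforced inside the enumeration wrapper: over-limit
paths are never yielded and never counted toward `k`, but they remain in
Yen's internal accepted list for spur generation. Dropping them there would
break completeness, because a within-limit path can be a Yen-descendant of
an over-limit one.

Zero-weight edges (S = 1) are legal; the lexicographic rule resolves the
resulting ties deterministically.

## Pair classification

A pair is classified `direct` whenever the master graph contains the
drug–mediator edge, even when a multi-hop path is lighter (a database edge
*is* a direct relation regardless of its confidence); otherwise the
weight-shortest path's intermediate count gives categories 1–3; pairs that
are disconnected, or reachable only through more than three intermediates,
are `unreachable`; pairs with an endpoint missing from the graph are
`not_in_db`. Whether hop-count or weight-based shortest paths should define
the category is genuinely open; weight-based is used because it matches the
path machinery users see, and the direct-edge-priority rule makes the two
agree on the category that matters most.

## Extensions

* **Single-source**: rank all chemical nodes by exact shortest-path
  distance to a mediator (ties by node id), keep the `k` closest, build each
  pair network with the same *N* and `max_intermediates`, and merge. Useful
  when the original compound is absent from the chemical database or when
  scouting compounds that might interact with a mediator.
* **Pathway-weighted**: build subnetworks from the drug to the mediator and
  to each of the mediator's differential-dependency-network (DDN) neighbors,
  merge all node sets (plus the mediator and every neighbor), then induce
  every master-graph edge among the merged set. Neighbors with no
  qualifying path — or absent from the graph entirely (unmapped gene
  symbols) — are retained as isolated nodes, so the DDN context is conserved
  in the output. Per-neighbor subnetworks reuse the pair's *N* and
  `max_intermediates`.
* **Condition-specific**: split DDN neighbors by the condition of their
  dependency edge (sensitive-specific, non-sensitive-specific, shared) and
  build one pathway-weighted network per condition; shared neighbors enter
  both sides by default (`specific_only` drops them, matching displays that
  show only condition-specific edges).

When both condition sides are built from disjoint specific neighbor sets,
their intersection always contains the plain drug–mediator subnetwork; it
can exceed it when the two neighbor subnetworks happen to share
intermediates, so only the superset direction is an invariant.

## Chemical identity

Compounds are matched to chemical nodes through InChIKeys: the query SMILES
is desalted by keeping the fragment with the most heavy atoms (ties to the
lexicographically smallest canonical fragment — a deterministic version of
the standard largest-fragment convention), stereo descriptors are stripped,
and the standard InChIKey is generated. Matching uses the key's first 14
characters (the connectivity block, which is stereo-independent), so all
stereoisomers and salt forms resolve to one merged (`CIDm`) node — the same
folding the chemical database applies with its own merged-compound ids.
Stereo stripping before hashing and block matching are redundant by design;
block matching is authoritative. The cheminformatics toolkit (RDKit) sits
behind a four-method backend protocol; nothing outside `chem_id` imports
chemistry machinery, so the graph and path layers run without a chemistry
stack.

## File formats and dialects

Parsers consume the STRING `protein.links.detailed` dialect (plus a
3-column combined-only variant), STITCH chemical–protein and
chemical–chemical dialects. Column identities come from the header by name;
unknown score columns are an error, not a silent skip. Scores outside
[0, 1000], malformed lines and wrong column counts raise parse errors with
line numbers. Self-loops are dropped with a logged warning. Duplicate
symmetric rows (the databases list each pair twice) must agree exactly in
protein files; chemical files merge collisions by per-channel maximum,
because `CIDs`→`CIDm` folding makes legitimate collisions routine. Graph
merging likewise takes the per-channel and combined maximum, making it
commutative, associative and idempotent. The writer emits one section per
dialect plus a node-list section (link files carry only edges; the node
list is what lets isolated nodes survive a round trip). A versioned JSON
graph store carries graphs, including aliases, across CLI invocations.

## Synthetic fixtures

Real STITCH/STRING downloads are deliberately not required. Two generators
stand in:

* **TOY-1**, a fixed 6-node graph (chemicals D, E; proteins A, B, C, M;
  seven edges; C isolated) whose entire D→M path structure is enumerable by
  hand: five simple paths with weights 0.3, 0.4, 0.7, 0.8, 1.0. The direct
  D–M edge (score 0.2, weight 0.8) is deliberately *not* the lightest
  route, so it separates the direct-edge classification rule from
  shortest-path logic.
* **A seeded random generator** emitting byte-identical flat files in the
  exact parser dialects for a given (spec, seed): node counts, edge density
  and per-channel (presence probability, mean) are configurable; scores are
  quantized to the 1/1000 grid; combined scores of channel-bearing edges
  are the noisy-OR of their sub-scores. Specs that would exceed 10⁶ edges
  are refused. The generator emulates the *format* and score structure of
  the real databases, not their degree distributions, score priors or
  biological correlations — so passing tests demonstrate algorithmic
  correctness on the dialects, not biological fidelity on real releases,
  which are version-dependent.

Default study sizes: test sweeps use graphs of ≤ 12 nodes (where exhaustive
simple-path enumeration is a feasible oracle) and fixture populations of a
few dozen nodes; the pair-network default is N = 10 distinct nodes and at
most 3 intermediate genes per path — large enough to show redundancy,
small enough to read.

## Exports

Viewer documents use the Cytoscape.js elements shape: node records carry a
role (source, target, intermediate, isolated, condition-specific neighbor);
edge records carry the effective score, an opacity equal to the score
clipped to [0.1, 1] (the floor keeps weak edges visible), a summary of any
edge-evidence annotations, and a templated outbound link to the public
database page for the pair. Shared DDN neighbors take the intermediate or
isolated role, since the role vocabulary is condition-specific. Documents
are validated with pydantic models (a JSON Schema is exported for other
consumers) and element order is sorted, so identical inputs give
byte-identical output. GraphML export goes through networkx with sorted
insertion and round-trips through standard readers.

## Known limitations

* Real-database reproduction is release-dependent; the package ships no
  download client and redistributes no STITCH/STRING data.
* The best-first search trades worst-case complexity for exact tie-breaks;
  graphs with enormous near-tie path families could be slow.
* Noisy-OR recombination ignores the databases' prior correction (see the
  discontinuity note above).
* Homolog substitution for compounds absent from the database is the
  user's choice (pass the substitute node id); no similarity search is
  provided.
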