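# evidencenet

Evidence networks for drug–mediator gene pairs: extract small, readable
sub-networks of best-evidenced paths linking a compound to a gene from a
STITCH/STRING-style chemical–protein interaction graph.

Statistical screens of drug response (e.g. differential-dependency analysis
of sensitive vs non-sensitive cancer cell lines) emit thousands of
drug–"mediator" gene pairs with no mechanistic context. `evidencenet`
contextualizes one pair at a time against a knowledge graph whose edges
carry per-channel evidence scores (experimental, database, text mining, …)
and a combined confidence `S ∈ [0, 1]`. Edges are costed `w = 1 − S`, so
minimum-weight paths are maximum-evidence association chains; loopless
paths from drug to mediator are enumerated in nondecreasing weight (Yen's
K-shortest paths over an exact, deterministically tie-broken search) and
merged until the sub-network holds at least *N* distinct nodes, keeping
only paths with at most 3 intermediate genes. Extensions build
single-source networks (a mediator and its *k* closest compounds),
pathway-weighted networks (subnetworks to each dependency-network neighbor
of the mediator, with all master-graph edges induced), and
condition-specific variants. See `docs/methods.md` for the full model.

Audience: computational biologists post-processing drug–gene screen hits,
and anyone who needs deterministic K-shortest-path subnetwork extraction
from STITCH/STRING-dialect flat files without a database server.

## Worked example

The bundled TOY-1 fixture has chemicals D, E and proteins A, B, C, M, with
combined scores D–A 0.9, A–M 0.8, D–B 0.7, B–M 0.9, A–B 0.5, D–M 0.2,
E–B 0.6 (C isolated):

```python
from evidencenet import build_evidence_network, classify_pair, k_shortest_paths
from evidencenet.fixtures import TOY1_IDS, TOY1_LABELS, toy1

graph = toy1()
D, M = TOY1_IDS["D"], TOY1_IDS["M"]

for path in k_shortest_paths(graph, D, M, k=10):
    labels = "-".join(TOY1_LABELS[n] for n in path.nodes)
    print(f"{labels:10s} weight={path.total_weight:.1f}")

net = build_evidence_network(graph, D, M, n_nodes=4)
print(sorted(TOY1_LABELS[n] for n in net.nodes), net.stop_reason)
print(classify_pair(graph, D, M).value)
```

prints

```
D-A-M      weight=0.3
D-B-M      weight=0.4
D-A-B-M    weight=0.7
D-M        weight=0.8
D-B-A-M    weight=1.0
['A', 'B', 'D', 'M'] node_threshold
direct
```

All five simple D→M paths come out in exact (weight, lexicographic) order.
With the stopping threshold N = 4, the network accepts D-A-M and D-B-M
(four distinct nodes) and stops. The pair classifies as `direct` because
the D–M edge exists in the graph — even though, at score 0.2, it is not the
lightest route; remove it and the pair classifies as `1` (one intermediate
gene on the best path).

The same flows are available from the shell:

```bash
evidencenet --seed 7 fixtures --n-proteins 8 --out fixtures/   # synthetic flat files
evidencenet build-graph --protein-links fixtures/protein_links.txt \
    --chemical-protein-links fixtures/chemical_protein_links.txt --out store.json
evidencenet pair --graph store.json --drug CIDm00000001 \
    --mediator 9606.P0004 --n-nodes 10 --format json --out net.json
evidencenet pair --graph store.json --drug CIDm00000001 \
    --mediator 9606.P0004 --channel-weight textmining=NONE --format graphml --out net.graphml
evidencenet classify --graph store.json --pairs pairs.tsv --out table.tsv
```

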