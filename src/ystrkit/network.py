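"""Median-joining haplotype networks for multistate STR data.

The construction follows the classic scheme: an epsilon-relaxed minimum
spanning network over weighted Manhattan (single-step) distances, iterative
addition of per-locus medians of triplets that strictly reduce the local
connection cost, pruning of obsolete median nodes, and an optional
maximum-parsimony post-processing step that removes links and medians
participating in no minimum-length spanning structure of the sampled
haplotypes.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import networkx as nx
import numpy as np

from .panels import LocusPanel, PopulationSample

__all__ = [
    "NetworkInput",
    "HaplotypeNetwork",
    "prepare_network_input",
    "minimum_spanning_network",
    "median_joining",
    "mp_prune",
    "export_network",
    "import_network",
]

DEFAULT_LOCUS_WEIGHT = 10.0  # NETWORK convention


@dataclass(frozen=True)
class NetworkInput:
    vector: tuple[int, ...]
    multiplicity: int
    labels: tuple[tuple[str, int], ...] = ()  # e.g. population tallies

    def label_counter(self) -> Counter:
        return Counter(dict(self.labels))


def _round_half_up_int(value: float) -> int:
    return math.floor(value + 0.5)


def prepare_network_input(
    sample: PopulationSample,
    panel_subset: LocusPanel | None = None,
    label_attribute: str = "population",
) -> tuple[list[NetworkInput], list[str], tuple[str, ...]]:
    """Collapse a sample to integer allele vectors for network building.

    Dual-copy loci are dropped; microvariant repeat numbers are rounded
    half-up to the nearest integer; records with a null or duplicated
    allele at an included locus are excluded.  Returns (entries, excluded
    sample ids, included locus names); identical vectors are collapsed with
    summed multiplicity and label tallies.
    """
    panel = panel_subset or sample.panel
    loci = tuple(l.name for l in panel if l.copy_number == 1)
    if not loci:
        raise ValueError("no single-copy loci to build the network on")
    excluded: list[str] = []
    tally: dict[tuple[int, ...], Counter] = {}
    mult: Counter = Counter()
    for rec in sample.records:
        vector: list[int] = []
        ok = True
        for locus in loci:
            a = rec.alleles[locus]
            if a.is_null or a.is_duplicated or len(a.values) != 1:
                ok = False
                break
            vector.append(_round_half_up_int(a.values[0]))
        if not ok:
            excluded.append(rec.sample_id)
            continue
        key = tuple(vector)
        mult[key] += 1
        label = getattr(rec, label_attribute, None)
        tally.setdefault(key, Counter())
        if label is not None:
            tally[key][label] += 1
    if not mult:
        raise ValueError("all records excluded; nothing to build a network from")
    entries = [
        NetworkInput(vec, mult[vec], tuple(sorted(tally[vec].items())))
        for vec in sorted(mult)
    ]
    return entries, excluded, loci


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # node attrs: vector, kind, multiplicity, labels
    loci: tuple[str, ...]
    weights: tuple[float, ...]
    epsilon: float
    metadata: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def sampled_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"]

    def median_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def distance(self, u: tuple[int, ...], v: tuple[int, ...]) -> float:
        return _dist(u, v, self.weights)

    def min_spanning_length(self, median_bound: int = 12) -> float:
        """Length of the shortest spanning structure of the sampled nodes
        using network links, minimized over subsets of median nodes
        (exhaustive up to ``median_bound`` medians, else MST upper bound)."""
        sampled = self.sampled_nodes()
        medians = self.median_nodes()
        if len(sampled) == 1 and not medians:
            return 0.0
        if len(medians) > median_bound:
            tree = nx.minimum_spanning_tree(self.graph, weight="weight")
            return float(sum(d["weight"] for _, _, d in tree.edges(data=True)))
        best = math.inf
        for r in range(len(medians) + 1):
            for subset in itertools.combinations(medians, r):
                nodes = set(sampled) | set(subset)
                sub = self.graph.subgraph(nodes)
                if not nx.is_connected(sub):
                    continue
                tree = nx.minimum_spanning_tree(sub, weight="weight")
                if set(tree.nodes) != nodes:
                    continue
                length = sum(d["weight"] for _, _, d in tree.edges(data=True))
                best = min(best, length)
        return float(best)


def _dist(u: Sequence[int], v: Sequence[int], weights: Sequence[float]) -> float:
    return float(sum(w * abs(a - b) for a, b, w in zip(u, v, weights)))


def _minimax_levels(nodes: list, weights: Sequence[float]) -> dict:
    """Single-linkage merge level (minimax/bottleneck distance) per pair."""
    n = len(nodes)
    pairs = {}
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(nodes[i], nodes[j], weights)
            dists.append((d, i, j))
    dists.sort()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for d, i, j in dists:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        for a in members[ri]:
            for b in members[rj]:
                pairs[(min(a, b), max(a, b))] = d
        parent[rj] = ri
        members[ri].extend(members[rj])
        del members[rj]
    return pairs


def _feasible_graph(
    nodes: list, weights: Sequence[float], epsilon: float
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network: link (u,v) is feasible iff
    d(u,v) <= bottleneck(u,v) + epsilon.  With epsilon 0 this contains every
    minimum spanning tree of the node set."""
    levels = _minimax_levels(nodes, weights)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (i, j), level in levels.items():
        d = _dist(nodes[i], nodes[j], weights)
        if d <= level + epsilon + 1e-9:
            g.add_edge(nodes[i], nodes[j], weight=d)
    return g


def minimum_spanning_network(
    vectors: Sequence[tuple[int, ...]],
    weights: Sequence[float] | None = None,
    epsilon: float = 0.0,
) -> nx.Graph:
    nodes = sorted(set(tuple(v) for v in vectors))
    if weights is None:
        weights = [DEFAULT_LOCUS_WEIGHT] * len(nodes[0])
    return _feasible_graph(nodes, weights, epsilon)


def _median(u: Sequence[int], v: Sequence[int], w: Sequence[int]) -> tuple[int, ...]:
    """Per-locus middle order statistic — the multistate median vector."""
    return tuple(sorted(t)[1] for t in zip(u, v, w))


def _triplets(graph: nx.Graph, exhaustive: bool):
    if exhaustive:
        yield from itertools.combinations(sorted(graph.nodes), 3)
    else:
        # connected triplets: both (u,v) and (v,w) feasible links
        for v in sorted(graph.nodes):
            neigh = sorted(graph.neighbors(v))
            for u, w in itertools.combinations(neigh, 2):
                yield u, v, w


def median_joining(
    entries: Sequence[NetworkInput] | Sequence[tuple[int, ...]],
    epsilon: float = 0.0,
    weights: Sequence[float] | None = None,
    loci: Sequence[str] | None = None,
    triplet_exhaustive_below: int = 30,
) -> HaplotypeNetwork:
    """Build a median-joining network from collapsed haplotype vectors.

    Iterates: epsilon-relaxed minimum spanning network -> add triplet
    medians that strictly reduce the local connection cost -> repeat; then
    deletes obsolete median nodes (degree <= 2, on no shortest sampled-pair
    path).  All orderings are lexicographic so output is deterministic.
    """
    norm: list[NetworkInput] = []
    for e in entries:
        if isinstance(e, NetworkInput):
            norm.append(e)
        else:
            norm.append(NetworkInput(tuple(int(x) for x in e), 1))
    if not norm:
        raise ValueError("no input vectors")
    by_vec: dict[tuple[int, ...], NetworkInput] = {}
    for e in norm:
        if e.vector in by_vec:
            prev = by_vec[e.vector]
            by_vec[e.vector] = NetworkInput(
                e.vector,
                prev.multiplicity + e.multiplicity,
                tuple(sorted((prev.label_counter() + e.label_counter()).items())),
            )
        else:
            by_vec[e.vector] = e
    sampled = sorted(by_vec)
    n_loci = len(sampled[0])
    if any(len(v) != n_loci for v in sampled):
        raise ValueError("vectors have inconsistent length")
    if weights is None:
        weights = [DEFAULT_LOCUS_WEIGHT] * n_loci
    weights = tuple(float(w) for w in weights)
    if any(w <= 0 for w in weights):
        raise ValueError("locus weights must be positive")
    if loci is None:
        loci = tuple(f"L{i + 1}" for i in range(n_loci))
    loci = tuple(loci)

    nodes: list[tuple[int, ...]] = list(sampled)
    if len(nodes) == 1:
        graph = nx.Graph()
        graph.add_node(nodes[0])
    else:
        graph = _feasible_graph(nodes, weights, epsilon)
        while True:
            exhaustive = len(nodes) <= triplet_exhaustive_below
            node_set = set(nodes)
            new_medians: set[tuple[int, ...]] = set()
            for u, v, w in _triplets(graph, exhaustive):
                m = _median(u, v, w)
                if m in node_set or m in new_medians:
                    continue
                direct = sorted(
                    (
                        _dist(u, v, weights),
                        _dist(u, w, weights),
                        _dist(v, w, weights),
                    )
                )
                local_cost = direct[0] + direct[1]  # MST of the triangle
                via_median = (
                    _dist(u, m, weights)
                    + _dist(v, m, weights)
                    + _dist(w, m, weights)
                )
                if via_median < local_cost - 1e-9:
                    new_medians.add(m)
            if not new_medians:
                break
            nodes = sorted(node_set | new_medians)
            graph = _feasible_graph(nodes, weights, epsilon)

    sampled_set = set(sampled)
    graph = _prune_obsolete(graph, sampled_set, weights, epsilon)

    out = nx.Graph()
    for vec in sorted(graph.nodes):
        entry = by_vec.get(vec)
        out.add_node(
            vec,
            vector=vec,
            kind="sampled" if entry else "median",
            multiplicity=entry.multiplicity if entry else 0,
            labels=dict(entry.labels) if entry else {},
        )
    for u, v in sorted(graph.edges):
        steps = {
            locus: int(v[i] - u[i]) for i, locus in enumerate(loci) if v[i] != u[i]
        }
        out.add_edge(u, v, weight=_dist(u, v, weights), steps=steps)
    return HaplotypeNetwork(out, loci, weights, epsilon, {"mp_pruned": False})


def _prune_obsolete(
    graph: nx.Graph,
    sampled: set,
    weights: Sequence[float],
    epsilon: float,
) -> nx.Graph:
    """Iteratively delete median nodes of degree <= 2 that lie on no
    shortest path between sampled nodes, rebuilding the spanning network
    over the remaining node set after each deletion."""
    nodes = sorted(graph.nodes)
    while True:
        if len(nodes) == 1:
            g = nx.Graph()
            g.add_node(nodes[0])
            return g
        g = _feasible_graph(nodes, weights, epsilon)
        base = _sampled_distances(g, sampled)
        removed = False
        for cand in sorted(set(nodes) - sampled):
            if g.degree(cand) > 2:
                continue
            trial_nodes = [n for n in nodes if n != cand]
            trial = _feasible_graph(trial_nodes, weights, epsilon)
            trial_d = _sampled_distances(trial, sampled)
            if trial_d is not None and all(
                trial_d[pair] <= base[pair] + 1e-9 for pair in base
            ):
                nodes = trial_nodes
                removed = True
                break
        if not removed:
            return g


def _sampled_distances(graph: nx.Graph, sampled: set) -> dict | None:
    out = {}
    present = [s for s in sampled if s in graph]
    for s in present:
        lengths = nx.single_source_dijkstra_path_length(graph, s, weight="weight")
        for t in present:
            if t <= s:
                continue
            if t not in lengths:
                return None  # disconnected
            out[(s, t)] = lengths[t]
    return out


# ---------------------------------------------------------------------------
# maximum-parsimony post-processing
# ---------------------------------------------------------------------------

def mp_prune(network: HaplotypeNetwork, exhaustive_bound: int = 20) -> HaplotypeNetwork:
    """Remove links and median nodes on no minimum-total-length spanning
    structure of the sampled nodes.

    Exhaustive (enumerate median subsets and all minimum spanning trees)
    when the network has at most ``exhaustive_bound`` links; otherwise a
    shortest-path-union heuristic is applied and flagged in metadata.
    """
    g = network.graph
    sampled = set(network.sampled_nodes())
    if g.number_of_edges() == 0:
        out = _copy_network(network, set(g.nodes), set())
        out.metadata.update({"mp_pruned": True, "mp_exhaustive": True})
        return out

    if g.number_of_edges() <= exhaustive_bound:
        keep_nodes, keep_edges = _mp_exhaustive(g, sampled, network.median_nodes())
        exhaustive = True
    else:
        keep_nodes, keep_edges = _mp_heuristic(g, sampled)
        exhaustive = False
    out = _copy_network(network, keep_nodes, keep_edges)
    out.metadata.update({"mp_pruned": True, "mp_exhaustive": exhaustive})
    return out


def _mp_exhaustive(g: nx.Graph, sampled: set, medians: list):
    best = math.inf
    optimal_trees = []
    for r in range(len(medians) + 1):
        for subset in itertools.combinations(sorted(medians), r):
            nodes = sampled | set(subset)
            sub = g.subgraph(nodes)
            if len(nodes) == 1:
                if best > 0:
                    best = 0.0
                    optimal_trees = [sub.copy()]
                continue
            if not nx.is_connected(sub):
                continue
            for tree in nx.SpanningTreeIterator(sub, weight="weight"):
                length = sum(d["weight"] for _, _, d in tree.edges(data=True))
                if length > best + 1e-9:
                    break
                if length < best - 1e-9:
                    best = length
                    optimal_trees = []
                optimal_trees.append(tree)
    keep_nodes: set = set()
    keep_edges: set = set()
    for tree in optimal_trees:
        length = sum(d["weight"] for _, _, d in tree.edges(data=True))
        if length > best + 1e-9:
            continue
        keep_nodes.update(tree.nodes)
        keep_edges.update(frozenset((u, v)) for u, v in tree.edges)
    return keep_nodes, keep_edges


def _mp_heuristic(g: nx.Graph, sampled: set):
    """Keep every edge lying on some shortest path between sampled nodes."""
    dist = {s: nx.single_source_dijkstra_path_length(g, s, weight="weight") for s in sampled}
    keep_edges: set = set()
    slist = sorted(sampled)
    for i, s in enumerate(slist):
        for t in slist[i + 1 :]:
            dst = dist[s].get(t)
            if dst is None:
                continue
            for u, v, d in g.edges(data=True):
                w = d["weight"]
                du_s, dv_s = dist[s].get(u), dist[s].get(v)
                du_t, dv_t = dist[t].get(u), dist[t].get(v)
                if None in (du_s, dv_s, du_t, dv_t):
                    continue
                on_path = (
                    abs(du_s + w + dv_t - dst) < 1e-9
                    or abs(dv_s + w + du_t - dst) < 1e-9
                )
                if on_path:
                    keep_edges.add(frozenset((u, v)))
    keep_nodes = set(sampled)
    for e in keep_edges:
        keep_nodes.update(e)
    return keep_nodes, keep_edges


def _copy_network(
    network: HaplotypeNetwork, keep_nodes: set, keep_edges: set
) -> HaplotypeNetwork:
    g = network.graph
    out = nx.Graph()
    for n in sorted(keep_nodes):
        out.add_node(n, **g.nodes[n])
    for u, v, d in g.edges(data=True):
        if frozenset((u, v)) in keep_edges:
            out.add_edge(u, v, **d)
    return HaplotypeNetwork(
        out, network.loci, network.weights, network.epsilon, dict(network.metadata)
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(
    network: HaplotypeNetwork,
    dest: Union[str, Path, TextIO],
    fmt: str = "tsv",
) -> None:
    """Write the network as a node + edge TSV stream, or as GML."""
    if fmt not in ("tsv", "gml"):
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'gml'")
    close = False
    if isinstance(dest, (str, Path)):
        mode = "w"
        dest = open(dest, mode, encoding="utf-8")
        close = True
    try:
        if fmt == "gml":
            g = nx.Graph()
            node_id = {n: i for i, n in enumerate(sorted(network.graph.nodes))}
            for n, d in network.graph.nodes(data=True):
                g.add_node(
                    node_id[n],
                    vector=",".join(map(str, n)),
                    kind=d["kind"],
                    multiplicity=d["multiplicity"],
                )
            for u, v, d in network.graph.edges(data=True):
                g.add_edge(node_id[u], node_id[v], weight=d["weight"])
            for line in nx.generate_gml(g):
                dest.write(line + "\n")
            return
        dest.write(f"#loci\t{','.join(network.loci)}\n")
        dest.write(f"#weights\t{','.join(f'{w:g}' for w in network.weights)}\n")
        dest.write(f"#epsilon\t{network.epsilon:g}\n")
        dest.write(f"#metadata\t{json.dumps(network.metadata, sort_keys=True)}\n")
        dest.write("NODE\tid\tvector\tkind\tmultiplicity\tlabels\n")
        node_id = {n: i for i, n in enumerate(sorted(network.graph.nodes))}
        for n in sorted(network.graph.nodes):
            d = network.graph.nodes[n]
            dest.write(
                f"NODE\t{node_id[n]}\t{','.join(map(str, n))}\t{d['kind']}"
                f"\t{d['multiplicity']}\t{json.dumps(d['labels'], sort_keys=True)}\n"
            )
        dest.write("EDGE\tu\tv\tweight\tsteps\n")
        for u, v in sorted(network.graph.edges):
            d = network.graph.edges[u, v]
            dest.write(
                f"EDGE\t{node_id[u]}\t{node_id[v]}\t{d['weight']:.10g}"
                f"\t{json.dumps(d['steps'], sort_keys=True)}\n"
            )
    finally:
        if close:
            dest.close()


def import_network(source: Union[str, Path, TextIO]) -> HaplotypeNetwork:
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, encoding="utf-8")
        close = True
    try:
        lines = [ln.rstrip("\n") for ln in source if ln.strip()]
    finally:
        if close:
            source.close()
    loci: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()
    epsilon = 0.0
    metadata: dict = {}
    nodes: dict[int, tuple] = {}
    g = nx.Graph()
    for ln in lines:
        cells = ln.split("\t")
        if cells[0] == "#loci":
            loci = tuple(cells[1].split(","))
        elif cells[0] == "#weights":
            weights = tuple(float(x) for x in cells[1].split(","))
        elif cells[0] == "#epsilon":
            epsilon = float(cells[1])
        elif cells[0] == "#metadata":
            metadata = json.loads(cells[1])
        elif cells[0] == "NODE" and cells[1] != "id":
            vec = tuple(int(x) for x in cells[2].split(","))
            nodes[int(cells[1])] = vec
            g.add_node(
                vec,
                vector=vec,
                kind=cells[3],
                multiplicity=int(cells[4]),
                labels=json.loads(cells[5]),
            )
        elif cells[0] == "EDGE" and cells[1] != "u":
            u = nodes[int(cells[1])]
            v = nodes[int(cells[2])]
            g.add_edge(u, v, weight=float(cells[3]), steps=json.loads(cells[4]))
    return HaplotypeNetwork(g, loci, weights, epsilon, metadata)
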