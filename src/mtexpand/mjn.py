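"""Median-joining haplotype networks.

Implements the Bandelt-style median-joining construction over a haplotype
table: the epsilon-relaxed minimum-spanning network (with epsilon = 0, the
union of all minimum spanning trees) is augmented iteratively with median
vectors — consensus sequences of connected triplets, the Steiner points of
the one-step mutation landscape — whenever they shorten the network, then
pruned of median vectors that no longer lie on any shortest path between
sampled haplotypes.  Interior, high-degree nodes of the result are read as
ancestral haplotypes; degree-1 nodes as derived, peripheral ones.

All tie-breaking is lexicographic (by node id, then by state), making the
output deterministic; the construction is order-sensitive in general, so
the tie-break rule is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .hapio import Alignment, HaplotypeTable, classify_sites, haplotype_alignment

__all__ = [
    "HaploNetwork",
    "build_mjn",
    "minimum_spanning_network",
    "network_stats",
    "write_edgelist",
    "write_graphml",
]


@dataclass(frozen=True)
class HaploNetwork:
    """Graph of sampled haplotypes plus inferred median vectors.

    ``graph`` nodes carry ``sampled`` (bool), ``frequency`` (0 for medians)
    and ``localities`` (count dict); edges carry ``weight`` (mutation count)
    and ``sites`` (tuple of differing reference positions).
    """

    graph: nx.Graph
    epsilon: int
    weights: tuple[float, ...]
    sampled: tuple[str, ...]

    @property
    def median_vectors(self) -> tuple[str, ...]:
        return tuple(
            v for v, d in self.graph.nodes(data=True) if not d["sampled"]
        )

    @property
    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _wdist(a: str, b: str, weights: tuple[float, ...]) -> float:
    return sum(w for x, y, w in zip(a, b, weights) if x != y)


def _diff_sites(a: str, b: str, sites: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(s for x, y, s in zip(a, b, sites) if x != y)


def minimum_spanning_network(
    seqs: dict[str, str],
    weights: tuple[float, ...],
    epsilon: float = 0,
) -> nx.Graph:
    """Epsilon-relaxed minimum-spanning network over the given sequences.

    With epsilon = 0 this is the union of all minimum spanning trees:
    processing distinct link lengths in increasing order, a link is feasible
    iff its endpoints are in different connected components at the *start*
    of its length class (Kruskal with equality grouping).  epsilon > 0
    additionally admits links up to epsilon longer than the length at which
    the components would first merge.
    """
    names = sorted(seqs)
    g = nx.Graph()
    g.add_nodes_from(names)
    edges = sorted(
        (_wdist(seqs[a], seqs[b], weights), a, b)
        for a, b in combinations(names, 2)
    )
    # group distances that are within epsilon of the class minimum
    comp = nx.utils.UnionFind(names)
    i = 0
    while i < len(edges):
        d0 = edges[i][0]
        j = i
        group = []
        while j < len(edges) and edges[j][0] <= d0 + epsilon:
            group.append(edges[j])
            j += 1
        snapshot = {n: comp[n] for n in names}
        for d, a, b in group:
            if snapshot[a] != snapshot[b]:
                g.add_edge(a, b, weight=d)
                comp.union(a, b)
        i = j
    return g


def _median_state(states: tuple[str, str, str]) -> str:
    """Majority state of a column triple; lexicographic smallest on ties."""
    best, best_count = None, -1
    for s in sorted(set(states)):
        c = states.count(s)
        if c > best_count:
            best, best_count = s, c
    return best


def _median_seq(a: str, b: str, c: str) -> str:
    return "".join(_median_state((x, y, z)) for x, y, z in zip(a, b, c))


def build_mjn(
    tbl: HaplotypeTable,
    epsilon: float = 0,
    weights: tuple[float, ...] | None = None,
    drop_indel_columns: bool = True,
    prune: bool = True,
    max_iter: int = 50,
) -> HaploNetwork:
    """Median-joining network of the haplotypes in ``tbl``.

    Alignment columns containing indels are removed first (the convention
    for control-region data, where gaps are treated as missing information).
    Site weights default to equal (1 per column).  Median vectors (named
    ``mv1``, ``mv2``, ... in order of creation) are added from connected
    triplets when their consensus sequence reduces total network length;
    the loop runs to fixpoint.  With ``prune`` (default), median vectors of
    degree < 2 or off every shortest sampled-to-sampled path are removed.
    """
    if tbl.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    aln = haplotype_alignment(tbl)
    if drop_indel_columns:
        cls = classify_sites(aln)
        aln = aln.drop_columns(cls.indel_containing)
    if weights is None:
        weights = (1.0,) * len(aln.sites)
    if len(weights) != len(aln.sites):
        raise ValueError("one weight per retained column required")
    seqs = dict(zip(aln.sample_ids, aln.matrix))
    if len(set(seqs.values())) < len(seqs):
        raise ValueError("duplicate haplotype rows; collapse first")
    sampled = tuple(aln.sample_ids)
    mv_serial = 0
    for _ in range(max_iter):
        g = minimum_spanning_network(seqs, weights, epsilon)
        current_len = sum(d["weight"] for _, _, d in g.edges(data=True))
        # candidate medians from connected triplets (u-v and u-w linked)
        candidates: dict[str, float] = {}
        for u in sorted(g.nodes):
            nbrs = sorted(g.neighbors(u))
            for v, w in combinations(nbrs, 2):
                m = _median_seq(seqs[u], seqs[v], seqs[w])
                if m in seqs.values() or m in candidates:
                    if m in candidates:
                        cost = sum(_wdist(m, seqs[x], weights) for x in (u, v, w))
                        candidates[m] = min(candidates[m], cost)
                    continue
                cost = sum(_wdist(m, seqs[x], weights) for x in (u, v, w))
                candidates[m] = cost
        if not candidates:
            break
        best_cost = min(candidates.values())
        added = False
        for m in sorted(s for s, c in candidates.items() if c == best_cost):
            trial = dict(seqs)
            mv_serial += 1
            name = f"mv{mv_serial}"
            trial[name] = m
            g2 = minimum_spanning_network(trial, weights, epsilon)
            new_len = sum(d["weight"] for _, _, d in g2.edges(data=True))
            if new_len < current_len:
                seqs = trial
                current_len = new_len
                added = True
            else:
                mv_serial -= 1
        if not added:
            break
    g = minimum_spanning_network(seqs, weights, epsilon)
    if prune:
        g, seqs = _prune_medians(g, seqs, sampled, weights, epsilon)
    for v in g.nodes:
        g.nodes[v]["sampled"] = v in sampled
        if v in sampled:
            i = tbl.haplotype_ids.index(v)
            g.nodes[v]["frequency"] = tbl.total_counts[i]
            g.nodes[v]["localities"] = {
                l: c for l, c in zip(tbl.localities, tbl.counts[i]) if c > 0
            }
        else:
            g.nodes[v]["frequency"] = 0
            g.nodes[v]["localities"] = {}
        g.nodes[v]["sequence"] = seqs[v]
    for a, b, d in g.edges(data=True):
        d["sites"] = _diff_sites(seqs[a], seqs[b], aln.sites)
        d["weight"] = int(d["weight"]) if float(d["weight"]).is_integer() else d["weight"]
    return HaploNetwork(graph=g, epsilon=epsilon, weights=weights, sampled=sampled)


def _prune_medians(g, seqs, sampled, weights, epsilon):
    """Drop median vectors of degree < 2 or off all shortest sampled paths."""
    while True:
        removed = False
        # degree-based pruning
        for v in sorted(g.nodes):
            if v not in sampled and g.degree(v) < 2:
                g.remove_node(v)
                seqs = {k: s for k, s in seqs.items() if k != v}
                removed = True
        if removed:
            g = minimum_spanning_network(seqs, weights, epsilon)
            continue
        # shortest-path pruning
        on_path: set[str] = set(sampled)
        for a, b in combinations(sorted(sampled), 2):
            try:
                paths = nx.all_shortest_paths(g, a, b, weight="weight")
            except nx.NetworkXNoPath:
                continue
            for p in paths:
                on_path.update(p)
        drop = [v for v in sorted(g.nodes) if v not in on_path]
        if not drop:
            break
        for v in drop:
            seqs.pop(v)
        g = minimum_spanning_network(seqs, weights, epsilon)
    return g, seqs


def network_stats(net: HaploNetwork) -> dict:
    """Degrees, peripheral haplotypes, and interior ranking.

    Degrees count all incident edges, including edges to median vectors.
    Peripheral = sampled nodes of degree 1; the interior ranking lists
    sampled nodes by descending degree (ties lexicographic).
    """
    degrees = {v: net.graph.degree(v) for v in net.sampled}
    peripheral = sorted(v for v, d in degrees.items() if d == 1)
    ranking = sorted(degrees, key=lambda v: (-degrees[v], v))
    return {
        "degrees": degrees,
        "peripheral": peripheral,
        "interior_ranking": ranking,
        "n_median_vectors": len(net.median_vectors),
        "total_length": net.total_length,
    }


def write_edgelist(net: HaploNetwork, path) -> None:
    """Edge-list TSV: node_a, node_b, n_mutations, comma-joined site list."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\tn_mutations\tsites\n")
        for a, b, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']}\t{','.join(map(str, d['sites']))}\n")


def write_graphml(net: HaploNetwork, path) -> None:
    """GraphML export with stringified composite attributes."""
    g = nx.Graph()
    for v, d in net.graph.nodes(data=True):
        g.add_node(
            v,
            sampled=bool(d["sampled"]),
            frequency=int(d["frequency"]),
            localities=";".join(f"{k}:{c}" for k, c in sorted(d["localities"].items())),
            sequence=d["sequence"],
        )
    for a, b, d in net.graph.edges(data=True):
        g.add_edge(a, b, weight=float(d["weight"]), sites=",".join(map(str, d["sites"])))
    nx.write_graphml(g, path)
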