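"""Median-joining network construction and topology analytics."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from mtexpand.mjn import (
    build_mjn,
    minimum_spanning_network,
    network_stats,
    write_edgelist,
    write_graphml,
)

from conftest import make_table


def brute_force_msn(seqs):
    """Union of all minimum spanning trees by exhaustive enumeration."""
    g = nx.Graph()
    names = sorted(seqs)
    g.add_nodes_from(names)
    for a, b in combinations(names, 2):
        g.add_edge(a, b, weight=sum(x != y for x, y in zip(seqs[a], seqs[b])))
    union = nx.Graph()
    union.add_nodes_from(names)
    best = None
    for t in nx.SpanningTreeIterator(g, minimum=True):
        w = t.size(weight="weight")
        if best is None:
            best = w
        if w > best + 1e-9:
            break
        union.add_edges_from(t.edges)
    return set(map(frozenset, union.edges))


def random_table(seed, max_hap=7, n_sites=8):
    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(4, max_hap + 1))
    while True:
        states = ["".join(rng.choice(list("ACGT"), n_sites)) for _ in range(n_hap)]
        if len(set(states)) == n_hap:
            return make_table(states)


class TestMSN:
    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_all_mst_union(self, seed):
        tbl = random_table(seed)
        seqs = dict(zip(tbl.haplotype_ids, tbl.states))
        msn = minimum_spanning_network(seqs, (1.0,) * 8)
        assert set(map(frozenset, msn.edges)) == brute_force_msn(seqs)

    def test_epsilon_relaxation_admits_longer_links(self):
        seqs = {"a": "AAAA", "b": "TAAA", "c": "TTAA"}
        strict = minimum_spanning_network(seqs, (1.0,) * 4, epsilon=0)
        relaxed = minimum_spanning_network(seqs, (1.0,) * 4, epsilon=1)
        assert strict.number_of_edges() == 2
        assert relaxed.number_of_edges() == 3  # a-c (distance 2) admitted


class TestBuildMJN:
    def test_two_haplotypes_single_edge(self):
        net = build_mjn(make_table(["AAAA", "TAAA"]))
        assert list(net.graph.edges(data="weight")) == [("h0", "h1", 1)]
        assert not net.median_vectors

    def test_three_star_steiner_point(self):
        # three haplotypes one step from an unsampled center (pairwise 2)
        net = build_mjn(make_table(["TAA", "ATA", "AAT"]))
        assert len(net.median_vectors) == 1
        mv = net.median_vectors[0]
        assert net.graph.degree(mv) == 3
        assert net.graph.nodes[mv]["sequence"] == "AAA"
        assert all(w == 1 for _, _, w in net.graph.edges(data="weight"))

    def test_median_never_increases_total_length(self):
        for seed in range(12):
            tbl = random_table(seed, max_hap=6, n_sites=6)
            seqs = dict(zip(tbl.haplotype_ids, tbl.states))
            msn_len = sum(
                d["weight"]
                for _, _, d in minimum_spanning_network(seqs, (1.0,) * 6).edges(data=True)
            )
            assert build_mjn(tbl, drop_indel_columns=False).total_length <= msn_len

    def test_equals_msn_when_no_admissible_medians(self):
        hits = 0
        for seed in range(20):
            tbl = random_table(seed)
            net = build_mjn(tbl, drop_indel_columns=False)
            if net.median_vectors:
                continue
            hits += 1
            seqs = dict(zip(tbl.haplotype_ids, tbl.states))
            assert set(map(frozenset, net.graph.edges)) == brute_force_msn(seqs)
        assert hits >= 3  # the seed range must actually exercise this path

    def test_network_spans_samples_within_mst_weight(self, cr_table):
        # Steiner property: the network connects every sampled haplotype,
        # and a spanning tree of the network costs no more than a minimum
        # spanning tree over the sampled haplotypes alone
        net = build_mjn(cr_table)
        g = net.graph
        assert nx.is_connected(g)
        seqs = {v: g.nodes[v]["sequence"] for v in g.nodes}
        sampled_complete = nx.Graph()
        for a, b in combinations(net.sampled, 2):
            sampled_complete.add_edge(
                a, b, weight=sum(x != y for x, y in zip(seqs[a], seqs[b]))
            )
        mst_sampled = nx.minimum_spanning_tree(sampled_complete).size(weight="weight")
        mst_network = nx.minimum_spanning_tree(g).size(weight="weight")
        assert mst_network <= mst_sampled

    def test_duplicate_rows_rejected(self):
        tbl = make_table(["AAAA", "AAAA", "TTTT"], ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="duplicate"):
            build_mjn(tbl)

    def test_median_vectors_have_degree_two_plus(self, cr_table):
        net = build_mjn(cr_table)
        assert all(net.graph.degree(v) >= 2 for v in net.median_vectors)


class TestJackalTopology:
    def test_eleven_peripheral_haplotypes(self, cr_table):
        st = network_stats(build_mjn(cr_table))
        assert len(st["peripheral"]) == 11

    def test_ind11_most_interior_with_six_connections(self, cr_table):
        st = network_stats(build_mjn(cr_table))
        assert st["interior_ranking"][0] == "Ind11"
        assert st["degrees"]["Ind11"] == 6
        assert max(st["degrees"].values()) == 6

    def test_four_connection_secondary_hubs(self, cr_table):
        degrees = network_stats(build_mjn(cr_table))["degrees"]
        assert {h for h, d in degrees.items() if d == 4} == {
            "Ind1", "Ind7", "Ind8", "Ind15",
        }

    def test_europe_and_israel_separation_from_india(self, cr_table):
        # after indel-column removal: Eur one substitution from its nearest
        # Indian haplotype, Isr two
        net = build_mjn(cr_table)
        seqs = {v: net.graph.nodes[v]["sequence"] for v in net.sampled}
        indians = [v for v in net.sampled if v not in ("Isr", "Eur")]
        dist = lambda a, b: sum(x != y for x, y in zip(seqs[a], seqs[b]))
        assert min(dist("Eur", h) for h in indians) == 1
        assert min(dist("Isr", h) for h in indians) == 2

    def test_star_center_degree(self):
        states = ["AAAAA", "TAAAA", "ATAAA", "AATAA", "AAATA", "AAAAT"]
        st = network_stats(build_mjn(make_table(states)))
        assert st["degrees"]["h0"] == 5
        assert all(st["degrees"][f"h{i}"] == 1 for i in range(1, 6))


class TestExports:
    def test_edgelist_and_graphml_round_trip(self, cr_table, tmp_path):
        net = build_mjn(cr_table)
        write_edgelist(net, tmp_path / "net.tsv")
        write_graphml(net, tmp_path / "net.graphml")
        lines = (tmp_path / "net.tsv").read_text().splitlines()
        assert lines[0] == "node_a\tnode_b\tn_mutations\tsites"
        assert len(lines) - 1 == net.graph.number_of_edges()
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert set(g.nodes) == set(net.graph.nodes)
        assert g.nodes["Ind5"]["frequency"] == 16
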