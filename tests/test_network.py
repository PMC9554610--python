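"""Greedy covering selection, interaction networks, components, export."""

import math

import networkx as nx
import numpy as np
import pytest

from spacernet import (
    Component,
    CoverInstance,
    MGERecord,
    SpacerCluster,
    build_host_mge_network,
    build_spacer_mge_network,
    connected_components,
    greedy_cover,
    module_type_report,
    read_network,
    select_hosts,
    select_mges,
    validate_network,
    write_network,
)
from spacernet.records import SpacerHit

from conftest import bfs_components, exhaustive_min_cover


def make_hit(cluster, mge, s_start=1, s_end=32, strand="+"):
    return SpacerHit(
        cluster_id=cluster,
        mge_id=mge,
        identity=1.0,
        aln_len=32,
        mismatches=0,
        gap_openings=0,
        q_start=1,
        q_end=32,
        s_start=s_start,
        s_end=s_end,
        evalue=1e-9,
        bitscore=50.0,
        qcov=1.0,
        strand=strand,
    )


class TestGreedyCover:
    def test_worked_instance(self):
        # A covers 3 first; B would then add only p4 while C adds p4,p5
        inst = CoverInstance(
            universe={"p1", "p2", "p3", "p4", "p5"},
            candidates={
                "A": {"p1", "p2", "p3"},
                "B": {"p3", "p4"},
                "C": {"p4", "p5"},
            },
        )
        assert greedy_cover(inst) == ["A", "C"]

    def test_single_candidate_covering_all(self):
        inst = CoverInstance({"x", "y"}, {"only": {"x", "y"}})
        assert greedy_cover(inst) == ["only"]

    def test_perfect_tie_lexicographic(self):
        inst = CoverInstance(
            {"p1", "p2"}, {"B": {"p1", "p2"}, "A": {"p1", "p2"}}
        )
        assert greedy_cover(inst) == ["A"]

    def test_uncoverable_universe_lists_missing(self):
        inst = CoverInstance({"p1", "p2"}, {"A": {"p1"}})
        with pytest.raises(ValueError, match="p2"):
            greedy_cover(inst)

    def test_candidate_outside_universe_rejected(self):
        inst = CoverInstance({"p1"}, {"A": {"p1", "zzz"}})
        with pytest.raises(ValueError, match="zzz"):
            greedy_cover(inst)

    def test_every_pick_contributes_and_cover_is_valid(self, rng):
        for _ in range(40):
            n_elem = int(rng.integers(3, 20))
            n_cand = int(rng.integers(2, 12))
            universe = {f"e{i}" for i in range(n_elem)}
            candidates = {}
            for j in range(n_cand):
                size = int(rng.integers(1, n_elem + 1))
                candidates[f"c{j:02d}"] = set(
                    rng.choice(sorted(universe), size=size, replace=False)
                )
            # force coverability
            leftovers = universe - set().union(*candidates.values())
            if leftovers:
                candidates["c_fix"] = leftovers
            sel = greedy_cover(CoverInstance(universe, candidates))
            covered = set()
            for cid in sel:
                assert candidates[cid] - covered  # contributed new elements
                covered |= candidates[cid]
            assert covered == universe

    def test_near_optimality_bound(self, rng):
        # |greedy| <= (1 + ln d) * |OPT| on small random instances
        for _ in range(30):
            n_elem = int(rng.integers(3, 12))
            n_cand = int(rng.integers(2, 8))
            universe = {f"e{i}" for i in range(n_elem)}
            candidates = {
                f"c{j}": set(
                    rng.choice(
                        sorted(universe),
                        size=int(rng.integers(1, n_elem + 1)),
                        replace=False,
                    )
                )
                for j in range(n_cand)
            }
            leftovers = universe - set().union(*candidates.values())
            if leftovers:
                candidates["c_fix"] = leftovers
            sel = greedy_cover(CoverInstance(universe, candidates))
            opt = exhaustive_min_cover(universe, candidates)
            d = max(len(s) for s in candidates.values())
            assert len(sel) <= (1 + math.log(d)) * opt

    def test_determinism_under_iteration_order(self):
        cands = {"A": {"p1", "p2"}, "B": {"p2", "p3"}, "C": {"p3"}}
        shuffled = dict(sorted(cands.items(), reverse=True))
        u = {"p1", "p2", "p3"}
        assert greedy_cover(CoverInstance(u, cands)) == greedy_cover(
            CoverInstance(u, shuffled)
        )


class TestSelection:
    def test_one_mge_covering_all_clusters(self):
        hits = [make_hit(f"S{i}", "Mbig", s_start=i * 50 + 1) for i in range(4)]
        hits += [make_hit("S0", "Msmall")]
        assert select_mges(hits) == ["Mbig"]

    def test_disjoint_hits_select_all_mges(self):
        hits = [make_hit("S1", "M1"), make_hit("S2", "M2"), make_hit("S3", "M3")]
        assert sorted(select_mges(hits)) == ["M1", "M2", "M3"]

    def test_worked_instance_as_hits(self):
        hits = (
            [make_hit(p, "A") for p in ("p1", "p2", "p3")]
            + [make_hit(p, "B") for p in ("p3", "p4")]
            + [make_hit(p, "C") for p in ("p4", "p5")]
        )
        assert select_mges(hits) == ["A", "C"]

    def test_no_hits_no_selection(self):
        assert select_mges([]) == []
        assert select_hosts([], {}) == []

    def test_single_host(self):
        hits = [make_hit("S1", "M1")]
        assert select_hosts(hits, {"S1": {"h1"}}) == ["h1"]

    def test_identical_repertoires_pick_lexicographic(self):
        hits = [make_hit("S1", "M1"), make_hit("S2", "M1", s_start=100)]
        hosts = {"S1": {"hB", "hA"}, "S2": {"hB", "hA"}}
        assert select_hosts(hits, hosts) == ["hA"]

    def test_three_host_worked_example(self):
        clusters = ["a", "b", "c", "d", "e"]
        hits = [make_hit(c, "M1", s_start=i * 40 + 1) for i, c in enumerate(clusters)]
        hosts = {
            "a": {"h1"},
            "b": {"h1"},
            "c": {"h1", "h2"},
            "d": {"h2", "h3"},
            "e": {"h3"},
        }
        assert select_hosts(hits, hosts) == ["h1", "h3"]


class TestNetworks:
    def test_minimal_spacer_mge_network(self):
        clusters = [SpacerCluster("S1", "A" * 32, ["m"], {"I-C"})]
        G = build_spacer_mge_network([make_hit("S1", "M1")], ["M1"], clusters)
        assert set(G.nodes) == {"S1", "M1"}
        assert G.edges["S1", "M1"]["n_matches"] == 1
        assert G.nodes["S1"]["crispr_type"] == "I-C"
        validate_network(G)

    def test_unselected_mge_absent(self):
        clusters = [SpacerCluster("S1", "A" * 32, ["m"])]
        hits = [make_hit("S1", "M1"), make_hit("S1", "M2")]
        G = build_spacer_mge_network(hits, ["M1"], clusters)
        assert "M2" not in G

    def test_two_loci_one_edge(self):
        clusters = [SpacerCluster("S1", "A" * 32, ["m"])]
        hits = [
            make_hit("S1", "M1", s_start=1, s_end=32),
            make_hit("S1", "M1", s_start=200, s_end=231),
        ]
        G = build_spacer_mge_network(hits, ["M1"], clusters)
        assert G.number_of_edges() == 1
        assert G.edges["S1", "M1"]["n_matches"] == 2

    def test_host_network_edge_and_counts(self):
        hits = [
            make_hit("S1", "M1", s_start=1, s_end=32),
            make_hit("S1", "M1", s_start=300, s_end=331),
        ]
        G = build_host_mge_network(hits, ["h1"], ["M1"], {"S1": {"h1"}})
        assert set(G.nodes) == {"h1", "M1"}
        assert G.edges["h1", "M1"]["n_matches"] == 2
        validate_network(G)

    def test_unmatched_host_absent(self):
        hits = [make_hit("S1", "M1")]
        G = build_host_mge_network(
            hits, ["h1", "h2"], ["M1"], {"S1": {"h1"}}
        )
        assert "h2" not in G

    def test_shared_cluster_two_hosts_two_edges(self):
        hits = [make_hit("S1", "M1")]
        G = build_host_mge_network(
            hits, ["h1", "h2"], ["M1"], {"S1": {"h1", "h2"}}
        )
        assert G.number_of_edges() == 2

    def test_mge_metadata_attached(self):
        clusters = [SpacerCluster("S1", "A" * 32, ["m"])]
        meta = {
            "M1": MGERecord(
                "M1", "ACGT", mge_class="plasmid", source_db="dbX",
                known_host="E. coli",
            )
        }
        G = build_spacer_mge_network([make_hit("S1", "M1")], ["M1"], clusters, meta)
        assert G.nodes["M1"]["mge_class"] == "plasmid"
        assert G.nodes["M1"]["known_host"] == "E. coli"

    def test_validate_rejects_same_kind_edge(self):
        G = nx.Graph()
        G.add_node("a", kind="spacer")
        G.add_node("b", kind="host")
        G.add_edge("a", "b")
        with pytest.raises(ValueError):
            validate_network(G)


class TestComponents:
    def test_two_disjoint_edges(self):
        G = nx.Graph()
        G.add_node("s1", kind="spacer")
        G.add_node("s2", kind="spacer")
        G.add_node("m1", kind="mge", mge_class="phage")
        G.add_node("m2", kind="mge", mge_class="phage")
        G.add_edge("s1", "m1")
        G.add_edge("s2", "m2")
        comps = connected_components(G)
        assert [c.n_nodes for c in comps] == [2, 2]
        assert comps[0].nodes[0] < comps[1].nodes[0]  # lexicographic tiebreak

    def test_path_is_one_component(self):
        G = nx.path_graph(4)
        assert len(connected_components(G)) == 1

    def test_matches_bfs_oracle_on_random_bipartite(self, rng):
        for _ in range(10):
            n_left = int(rng.integers(5, 26))
            n_right = int(rng.integers(5, 26))
            left = [f"s{i}" for i in range(n_left)]
            right = [f"m{i}" for i in range(n_right)]
            G = nx.Graph()
            for n in left:
                G.add_node(n, kind="spacer")
            for n in right:
                G.add_node(n, kind="mge", mge_class="phage")
            edges = []
            for u in left:
                for v in right:
                    if rng.random() < 0.06:
                        edges.append((u, v))
                        G.add_edge(u, v)
            expected = {
                frozenset(c) for c in bfs_components(left + right, edges)
            }
            got = {frozenset(c.nodes) for c in connected_components(G)}
            assert got == expected

    def test_ordering_by_size_descending(self, rng):
        G = nx.Graph()
        for i in range(3):  # component of 4 nodes
            G.add_edge(f"a{i}", f"a{i+1}")
        G.add_edge("b0", "b1")  # component of 2 nodes
        sizes = [c.n_nodes for c in connected_components(G)]
        assert sizes == sorted(sizes, reverse=True)


class TestModuleReport:
    def _graph(self, spacer_types, n_phages, n_plasmids=0, n_hosts=0):
        G = nx.Graph()
        mges = []
        for i in range(n_phages):
            G.add_node(f"ph{i}", kind="mge", mge_class="phage")
            mges.append(f"ph{i}")
        for i in range(n_plasmids):
            G.add_node(f"pl{i}", kind="mge", mge_class="plasmid")
            mges.append(f"pl{i}")
        for i, t in enumerate(spacer_types):
            node = f"s{i}"
            G.add_node(node, kind="spacer", crispr_type=t or "untyped")
            G.add_edge(node, mges[i % len(mges)])
        for m in mges[1:]:  # keep the module connected
            G.add_edge("s0", m)
        for i in range(n_hosts):
            G.add_node(f"h{i}", kind="host")
            G.add_edge(f"h{i}", mges[0])
        return G

    def test_basic_counts(self):
        G = self._graph(["I-C", "I-C"], n_phages=1)
        comp = connected_components(G)[0]
        report = module_type_report(comp, G)
        assert report["spacers_by_type"] == {"I-C": 2}
        assert report["n_phages"] == 1
        assert report["n_plasmids"] == 0

    def test_untyped_label(self):
        G = self._graph([None, None], n_phages=1)
        comp = connected_components(G)[0]
        assert module_type_report(comp, G)["spacers_by_type"] == {"untyped": 2}

    def test_mixed_type_module(self):
        # a module dominated by one CRISPR-Cas type: 59 II-C vs 2 I-C
        # spacers targeting 4 phages
        G = self._graph(["II-C"] * 59 + ["I-C"] * 2, n_phages=4)
        comp = connected_components(G)[0]
        report = module_type_report(comp, G)
        assert report["spacers_by_type"] == {"II-C": 59, "I-C": 2}
        assert report["n_phages"] == 4


class TestExport:
    def _network(self):
        clusters = [SpacerCluster("S 1", "A" * 32, ["m"], {"I-C"})]
        return build_spacer_mge_network(
            [make_hit("S 1", "M1")], ["M1"], clusters
        )

    def test_gml_roundtrip(self, tmp_path):
        G = self._network()
        path = str(tmp_path / "net.gml")
        write_network(G, path)
        H = read_network(path)
        assert set(H.nodes) == set(G.nodes)  # ids with spaces preserved
        assert set(map(frozenset, H.edges)) == set(map(frozenset, G.edges))
        for n in G.nodes:
            assert dict(H.nodes[n]) == dict(G.nodes[n])
        for u, v in G.edges:
            assert H.edges[u, v]["n_matches"] == G.edges[u, v]["n_matches"]

    def test_empty_network_file(self, tmp_path):
        path = str(tmp_path / "empty.gml")
        write_network(nx.Graph(), path)
        assert read_network(path).number_of_nodes() == 0

    def test_tsv_tables(self, tmp_path):
        prefix = str(tmp_path / "net")
        write_network(self._network(), prefix, format="tsv")
        nodes = (tmp_path / "net.nodes.tsv").read_text().splitlines()
        edges = (tmp_path / "net.edges.tsv").read_text().splitlines()
        assert nodes[0].startswith("id\t")
        assert len(nodes) == 3 and len(edges) == 2

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_network(self._network(), str(tmp_path / "x"), format="dot")
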