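"""Residue interaction networks: construction against threshold oracles,
FIR clustering against union-find, butterfly-region rules, network
diffs, and lossless export."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, strategies as st

from tandemptp.annotations import FIRSet, demo_firs, demo_motifs
from tandemptp.network import (
    build_network,
    classify_regions,
    compare_networks,
    export_graph,
    extract_fir_subnetwork,
    find_clusters,
    import_graph,
)
from tandemptp.synthetic import contact_matrix_from_pairs


class UnionFind:
    """Independent connected-components oracle."""

    def __init__(self, nodes):
        self.parent = {n: n for n in nodes}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)

    def components(self):
        groups = {}
        for n in self.parent:
            groups.setdefault(self.find(n), set()).add(n)
        return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


class TestBuildNetwork:
    def test_empty_adjacency_gives_edgeless_graph(self):
        cm = contact_matrix_from_pairs(10, [], background_distance=9.0)
        # neighbor band excluded by min_seq_sep, nothing else in contact
        net = build_network(cm)
        assert net.number_of_nodes() == 10
        assert net.number_of_edges() == 0

    def test_fully_adjacent_four_residues_yield_three_edges(self):
        # all pairs in contact; neighbor exclusion leaves |i-j| >= 2:
        # (0,2), (0,3), (1,3)
        cm = contact_matrix_from_pairs(
            4, [(i, j) for i in range(4) for j in range(i + 1, 4)]
        )
        net = build_network(cm)
        assert set(map(tuple, map(sorted, net.edges))) == {(0, 2), (0, 3), (1, 3)}

    def test_random_matrices_match_threshold_scan_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            pairs = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            cm = contact_matrix_from_pairs(n, pairs)
            net = build_network(cm, min_seq_sep=2)
            expected = {
                frozenset((i, j))
                for i in range(n)
                for j in range(i + 1, n)
                if cm.mean_distance[i, j] < cm.cutoff and j - i >= 2
            }
            assert {frozenset(e) for e in net.edges} == expected

    def test_fir_outside_matrix_rejected(self):
        cm = contact_matrix_from_pairs(10, [])
        firs = demo_firs()  # residues up to 29
        with pytest.raises(ValueError, match="outside matrix range"):
            build_network(cm, firs=firs)

    def test_edge_weights_are_mean_distances(self):
        cm = contact_matrix_from_pairs(6, [(0, 3)], contact_distance=4.2)
        net = build_network(cm)
        assert net.edges[0, 3]["weight"] == pytest.approx(4.2)


def d1_like_network(extra_pairs=(), drop_pairs=()):
    """A D1-domain-like FIR scenario: active site, WPD loop and
    substrate-recognition residues mutually in contact; Q loop and
    R loop/Glu each clustering separately."""
    firs = demo_firs()
    groups = {}
    for name, (idx, group) in firs.members.items():
        groups.setdefault(group, []).append(idx)
    pairs = set()

    def connect(residues):
        # all within-set pairs at sequence separation >= 2, so every edge
        # stays inside the set and survives neighbor exclusion
        residues = sorted(residues)
        for a in residues:
            for b in residues:
                if b - a >= 2:
                    pairs.add((a, b))

    # tight network among active site + WPD + recognition
    connect(groups["active_site"] + groups["WPD_loop"] + groups["substrate_recognition"])
    connect(groups["Q_loop"])
    connect(groups["R_loop_and_Glu"])
    pairs |= set(extra_pairs)
    pairs -= set(drop_pairs)
    cm = contact_matrix_from_pairs(30, sorted(pairs))
    motifs = demo_motifs(30)
    net = build_network(cm, motifs=motifs, firs=firs)
    return net, firs, motifs


class TestFIRSubnetwork:
    def test_edgeless_subnetwork_gives_twenty_singletons(self):
        cm = contact_matrix_from_pairs(30, [])
        firs = demo_firs()
        sub = extract_fir_subnetwork(build_network(cm, firs=firs), firs)
        clusters = find_clusters(sub)
        assert len(clusters) == 20
        assert clusters["cluster"].nunique() == 20
        assert (clusters["cluster_size"] == 1).all()

    def test_d1_like_matrix_joins_catalytic_groups(self):
        # active site, WPD loop and recognition residues form one cluster
        net, firs, _ = d1_like_network()
        sub = extract_fir_subnetwork(net, firs)
        clusters = find_clusters(sub)
        top = clusters[clusters["cluster"] == 0]
        top_groups = set(top["fir_group"])
        assert {"active_site", "WPD_loop", "substrate_recognition"} <= top_groups
        assert "Q_loop" not in top_groups
        assert "R_loop_and_Glu" not in top_groups

    def test_components_match_union_find_oracle(self, rng):
        # 500 random graphs
        for _ in range(500):
            n = int(rng.integers(3, 15))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            uf = UnionFind(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        g.add_edge(i, j)
                        uf.union(i, j)
            clusters = find_clusters(g)
            got = [
                set(clusters[clusters["cluster"] == c]["residue"])
                for c in sorted(clusters["cluster"].unique())
            ]
            assert got == uf.components()

    def test_subgraph_edges_are_subset_of_parent(self):
        net, firs, _ = d1_like_network()
        sub = extract_fir_subnetwork(net, firs)
        assert {frozenset(e) for e in sub.edges} <= {frozenset(e) for e in net.edges}

    def test_cluster_count_monotone_in_cutoff(self):
        # more permissive cutoff -> more edges -> fewer or equal components
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 15, size=(1, 12, 3))
        from conftest import make_trajectory
        from tandemptp.contacts import compute_contact_matrix

        traj = make_trajectory(coords)
        prev = None
        for cutoff in [3.0, 5.0, 8.0, 12.0]:
            cm = compute_contact_matrix(traj, cutoff=cutoff)
            net = build_network(cm)
            n_comp = nx.number_connected_components(net)
            if prev is not None:
                assert n_comp <= prev
            prev = n_comp


class TestClassifyRegions:
    def test_single_motif_and_cross_motif_rules(self):
        motifs = demo_motifs(30)
        cm = contact_matrix_from_pairs(30, [(0, 2), (7, 16), (0, 25), (6, 22)])
        net = build_network(cm, motifs=motifs)
        labels = classify_regions(net, motifs)
        assert labels[(0, 2)] == "head"          # within motif 1
        assert labels[(7, 16)] == "body-wings"   # motif 3 - motif 6
        assert labels[(0, 25)] == "head"          # head precedence over tail
        assert labels[(6, 22)] == "tail"          # motif 3 - motif 8

    def test_matches_exhaustive_rule_oracle(self, rng):
        motifs = demo_motifs(30)
        motif_of = motifs.motif_of()
        pairs = [
            (i, j) for i in range(30) for j in range(i + 2, 30) if rng.random() < 0.2
        ]
        net = build_network(contact_matrix_from_pairs(30, pairs), motifs=motifs)
        labels = classify_regions(net, motifs)
        for (u, v), lab in labels.items():
            mu, mv = motif_of.get(u), motif_of.get(v)
            if 1 in (mu, mv):
                expected = "head"
            elif mu in (8, 9, 10) or mv in (8, 9, 10):
                expected = "tail"
            elif mu in range(2, 8) and mv in range(2, 8):
                expected = "body-wings"
            else:
                expected = "unassigned"
            assert lab == expected


class TestCompareNetworks:
    def test_identical_networks_have_no_differences(self):
        net, _, motifs = d1_like_network()
        cmp = compare_networks(net, net, motifs=motifs)
        assert not cmp.only_in_a and not cmp.only_in_b
        assert cmp.shared == {frozenset(e) for e in net.edges}

    def test_uncoupled_q_loop_r_loop_edge_appears_in_diff(self):
        # D1 alone: Q-loop glutamine contacts the R loop; tethering D2
        # uncouples it -> the edge shows up as only-in-A
        q_r_edge = (26, 24)  # a Q_loop residue and an R_loop residue
        alone, firs, motifs = d1_like_network(extra_pairs=[tuple(sorted(q_r_edge))])
        tandem, _, _ = d1_like_network()
        cmp = compare_networks(alone, tandem, motifs=motifs)
        assert frozenset(q_r_edge) in cmp.only_in_a
        assert frozenset(q_r_edge) not in cmp.only_in_b
        # and the Q loop no longer reaches the R loop in the tandem network
        sub = extract_fir_subnetwork(tandem, firs)
        clusters = find_clusters(sub)
        by_res = clusters.set_index("residue")
        assert by_res.loc[26, "cluster"] != by_res.loc[24, "cluster"]

    def test_antisymmetry(self):
        a, _, motifs = d1_like_network(extra_pairs=[(2, 16)])
        b, _, _ = d1_like_network(extra_pairs=[(4, 21)])
        ab = compare_networks(a, b, motifs=motifs)
        ba = compare_networks(b, a, motifs=motifs)
        assert ab.only_in_a == ba.only_in_b
        assert ab.only_in_b == ba.only_in_a
        assert ab.shared == ba.shared

    def test_matches_brute_force_set_operations(self, rng):
        for _ in range(50):
            n = 12
            pairs_a = [(i, j) for i in range(n) for j in range(i + 2, n) if rng.random() < 0.25]
            pairs_b = [(i, j) for i in range(n) for j in range(i + 2, n) if rng.random() < 0.25]
            a = build_network(contact_matrix_from_pairs(n, pairs_a))
            b = build_network(contact_matrix_from_pairs(n, pairs_b))
            cmp = compare_networks(a, b)
            ea = {frozenset(e) for e in a.edges}
            eb = {frozenset(e) for e in b.edges}
            assert cmp.only_in_a == ea - eb
            assert cmp.only_in_b == eb - ea
            assert cmp.shared == ea & eb
            # the three sets partition the union
            assert cmp.only_in_a | cmp.only_in_b | cmp.shared == ea | eb
            assert not (cmp.only_in_a & cmp.only_in_b)

    def test_unmapped_node_with_edges_rejected(self):
        a = build_network(contact_matrix_from_pairs(6, [(0, 3)]))
        b = build_network(contact_matrix_from_pairs(6, [(0, 3)]))
        mapping = {n: n for n in a.nodes if n != 0}
        with pytest.raises(ValueError, match="unmapped"):
            compare_networks(a, b, node_mapping=mapping)


class TestExport:
    def test_graphml_round_trip_is_lossless(self, tmp_path):
        net, _, _ = d1_like_network()
        path = tmp_path / "net.graphml"
        export_graph(net, path, format="graphml")
        back = import_graph(path)
        assert set(back.nodes) == set(net.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.edges}
        for n in net.nodes:
            for key, val in net.nodes[n].items():
                assert back.nodes[n][key] == val
        for u, v in net.edges:
            assert back.edges[u, v]["weight"] == pytest.approx(net.edges[u, v]["weight"])

    def test_edgeless_graph_round_trips(self, tmp_path):
        net = build_network(contact_matrix_from_pairs(5, []))
        path = tmp_path / "empty.graphml"
        export_graph(net, path)
        assert import_graph(path).number_of_nodes() == 5

    def test_sif_export_contains_all_edges(self, tmp_path):
        net, _, _ = d1_like_network()
        path = tmp_path / "net.sif"
        export_graph(net, path, format="sif")
        lines = [l for l in path.read_text().splitlines() if "\t" in l]
        assert len(lines) == net.number_of_edges()

    def test_exported_edge_counts_match_for_random_graphs(self, rng, tmp_path):
        for k in range(20):
            n = int(rng.integers(3, 10))
            pairs = [(i, j) for i in range(n) for j in range(i + 2, n) if rng.random() < 0.4]
            net = build_network(contact_matrix_from_pairs(n, pairs))
            path = tmp_path / f"g{k}.graphml"
            export_graph(net, path)
            assert import_graph(path).number_of_edges() == net.number_of_edges()

    def test_unsupported_format_rejected(self, tmp_path):
        net = build_network(contact_matrix_from_pairs(4, []))
        with pytest.raises(ValueError, match="unsupported"):
            export_graph(net, tmp_path / "x.bin", format="bin")


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fir_groups_always_partition_into_five(seed):
    # any shuffled relabelling of the demo FIR set keeps the five groups
    rng = np.random.default_rng(seed)
    firs = demo_firs()
    names = list(firs.members)
    rng.shuffle(names)
    shuffled = FIRSet(members={n: firs.members[n] for n in names})
    assert shuffled.groups_present() == set(
        ("active_site", "substrate_recognition", "WPD_loop", "Q_loop", "R_loop_and_Glu")
    )
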