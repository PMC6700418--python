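"""Genus-pair projection, donor presence, clustering, cluster networks."""

import numpy as np
import pandas as pd
import pytest

from interflora import community as com
from interflora.scoring import ScoredPair


def sp(ka, kb, score=0.8):
    return ScoredPair(ka, kb, 1.0, score, score)


def genus_table(carriers):
    """carriers: {ko: set of genera}; abundance 1.0 where carried."""
    genera = sorted({g for gs in carriers.values() for g in gs})
    data = {g: [1.0 if g in carriers[k] else 0.0 for k in carriers] for g in genera}
    return pd.DataFrame(data, index=list(carriers))


class TestKoPairsToGenusPairs:
    def test_single_pair(self):
        table = genus_table({"K00001": {"G1"}, "K00002": {"G2"}})
        (gp,) = com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], table)
        assert gp.key == ("G1", "G2")
        assert gp.supporting_ko_pairs == [("K00001", "K00002")]
        assert gp.aggregate_score == pytest.approx(0.8)

    def test_same_genus_pair_excluded(self):
        table = genus_table({"K00001": {"G1"}, "K00002": {"G1"}})
        assert com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], table) == []

    def test_matches_cross_product_enumeration(self):
        table = genus_table({"K00001": {"G1", "G2"}, "K00002": {"G2", "G3"}})
        gps = com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], table)
        assert {g.key for g in gps} == {("G1", "G2"), ("G1", "G3"), ("G2", "G3")}

    def test_symmetric_in_ko_and_genus_order(self):
        t1 = genus_table({"K00001": {"G1", "G3"}, "K00002": {"G2"}})
        t2 = t1[sorted(t1.columns, reverse=True)]
        a = com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], t1)
        b = com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], t2)
        assert {g.key for g in a} == {g.key for g in b}

    def test_strict_complement_drops_shared_genera(self):
        table = genus_table({"K00001": {"G1", "G2"}, "K00002": {"G2", "G3"}})
        gps = com.ko_pairs_to_genus_pairs(
            [sp("K00001", "K00002")], table, strict_complement=True
        )
        # G2 carries both KOs, so only G1 (A-side) x G3 (B-side) remains
        assert {g.key for g in gps} == {("G1", "G3")}

    def test_supporters_deduplicated_per_ko_pair(self):
        table = genus_table({"K00001": {"G1", "G2"}, "K00002": {"G1", "G2"}})
        (gp,) = com.ko_pairs_to_genus_pairs([sp("K00001", "K00002")], table)
        assert gp.key == ("G1", "G2")
        assert gp.supporting_ko_pairs == [("K00001", "K00002")]

    def test_aggregate_at_least_mean(self):
        table = genus_table({"K00001": {"G1"}, "K00002": {"G2"}, "K00003": {"G1"}, "K00004": {"G2"}})
        gps = com.ko_pairs_to_genus_pairs(
            [sp("K00001", "K00002", 0.7), sp("K00003", "K00004", 0.9)], table
        )
        (gp,) = gps
        assert gp.aggregate_score >= gp.mean_score


def donor_table(carriers):
    return genus_table(carriers)


class TestDonorPresence:
    def test_missing_genus_gives_zero(self):
        gps = com.ko_pairs_to_genus_pairs(
            [sp("K00001", "K00002")], genus_table({"K00001": {"G1"}, "K00002": {"G2"}})
        )
        tables = {"d1": donor_table({"K00001": {"G1"}, "K00002": set()})}
        mat = com.donor_presence(gps, tables)
        assert mat.matrix.tolist() == [[0]]

    def test_both_sides_detected_gives_one(self):
        gps = com.ko_pairs_to_genus_pairs(
            [sp("K00001", "K00002")], genus_table({"K00001": {"G1"}, "K00002": {"G2"}})
        )
        tables = {"d1": donor_table({"K00001": {"G1"}, "K00002": {"G2"}})}
        mat = com.donor_presence(gps, tables)
        assert mat.matrix.tolist() == [[1]]

    def test_matches_brute_force(self, rng):
        kos = [f"K{i:05d}" for i in range(1, 11)]
        genera = [f"G{i}" for i in range(1, 6)]
        carriers = {k: {g for g in genera if rng.random() < 0.5} for k in kos}
        table = genus_table(carriers)
        pairs = [sp(kos[2 * i], kos[2 * i + 1]) for i in range(5)]
        gps = com.ko_pairs_to_genus_pairs(pairs, table)
        tables = {}
        for d in range(10):
            dc = {k: {g for g in carriers[k] if rng.random() < 0.7} for k in kos}
            tables[f"d{d:02d}"] = donor_table(dc)
        mat = com.donor_presence(gps, tables)
        for i, donor in enumerate(mat.donors):
            t = tables[donor]
            for j, gp in enumerate(gps):
                expected = 0
                for ka, kb in gp.supporting_ko_pairs:
                    def det(ko, g):
                        return g in t.columns and ko in t.index and t.at[ko, g] > 0
                    if (det(ka, gp.genus_a) and det(kb, gp.genus_b)) or (
                        det(kb, gp.genus_a) and det(ka, gp.genus_b)
                    ):
                        expected = 1
                        break
                assert mat.matrix[i, j] == expected


class TestSplitCommon:
    def make_matrix(self, mat, donors=None, keys=None):
        mat = np.asarray(mat)
        donors = donors or [f"d{i}" for i in range(mat.shape[0])]
        keys = keys or [(f"Ga{j}", f"Gb{j}") for j in range(mat.shape[1])]
        return com.DonorPresenceMatrix(donors, keys, mat)

    def test_all_present_is_common(self):
        m = self.make_matrix([[1], [1], [1]])
        common, specific = com.split_common(m, 0.9)
        assert common == m.pair_keys
        assert specific.matrix.shape == (3, 0)

    def test_absent_everywhere_is_specific(self):
        m = self.make_matrix([[0], [0]])
        common, specific = com.split_common(m, 0.9)
        assert common == []
        assert specific.pair_keys == m.pair_keys

    def test_partition_matches_column_mean_filter(self, rng):
        m = self.make_matrix(rng.integers(0, 2, (12, 20)))
        common, specific = com.split_common(m, 0.5)
        frac = m.matrix.mean(axis=0)
        expected_common = [k for k, f in zip(m.pair_keys, frac) if f >= 0.5]
        assert common == expected_common
        assert set(common) | set(specific.pair_keys) == set(m.pair_keys)
        assert not set(common) & set(specific.pair_keys)


class TestClusterDonors:
    def block_matrix(self, n_per_block=4, n_blocks=3, width=6):
        rows, donors = [], []
        for b in range(n_blocks):
            sig = [1 if width * b <= j < width * (b + 1) else 0 for j in range(width * n_blocks)]
            for i in range(n_per_block):
                rows.append(sig)
                donors.append(f"d{b}_{i}")
        keys = [(f"Ga{j}", f"Gb{j}") for j in range(width * n_blocks)]
        return com.DonorPresenceMatrix(donors, keys, np.array(rows)), [
            b for b in range(n_blocks) for _ in range(n_per_block)
        ]

    def test_identical_donors_single_cluster(self):
        m = com.DonorPresenceMatrix(["d1", "d2"], [("A", "B")], np.array([[1], [1]]))
        cl = com.cluster_donors(m, n_clusters=1)
        assert cl.n_clusters == 1

    def test_disjoint_donors_two_singletons(self):
        m = com.DonorPresenceMatrix(
            ["d1", "d2"], [("A", "B"), ("C", "D")], np.array([[1, 0], [0, 1]])
        )
        cl = com.cluster_donors(m, n_clusters=2)
        assert cl.assignment["d1"] != cl.assignment["d2"]

    def test_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        m, truth = self.block_matrix()
        cl = com.cluster_donors(m, n_clusters=3)
        pred = [cl.assignment[d] for d in m.donors]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_permutation_stability(self, rng):
        from sklearn.metrics import adjusted_rand_score

        m, _ = self.block_matrix()
        perm = rng.permutation(len(m.donors))
        shuffled = com.DonorPresenceMatrix(
            [m.donors[i] for i in perm], list(m.pair_keys), m.matrix[perm]
        )
        a = com.cluster_donors(m, n_clusters=3)
        b = com.cluster_donors(shuffled, n_clusters=3)
        donors = m.donors
        assert (
            adjusted_rand_score(
                [a.assignment[d] for d in donors], [b.assignment[d] for d in donors]
            )
            == 1.0
        )

    def test_too_many_clusters_errors(self):
        m = com.DonorPresenceMatrix(["d1"], [("A", "B")], np.array([[1]]))
        with pytest.raises(ValueError, match="exceeds"):
            com.cluster_donors(m, n_clusters=2)


class TestExportClusterNetwork:
    def setup_pairs(self):
        gps = []
        # 6 genera in a path: aggregates 20, 5, 30
        specs = [("G1", "G2", 20.0), ("G3", "G4", 5.0), ("G5", "G6", 30.0)]
        for a, b, agg in specs:
            gp = com.GenusPair(a, b)
            gp.supporting_ko_pairs.append(("K00001", "K00002"))
            gp.supporter_scores.append(agg)
            gps.append(gp)
        keys = [g.key for g in gps]
        presence = com.DonorPresenceMatrix(["d1"], keys, np.ones((1, 3), dtype=int))
        return gps, presence

    def test_filter_drops_weak_edges(self):
        gps, presence = self.setup_pairs()
        g = com.export_cluster_network(["d1"], gps, presence, edge_min_aggregate=15.0)
        assert set(map(tuple, map(sorted, g.edges))) == {("G1", "G2"), ("G5", "G6")}

    def test_all_below_threshold_empty_unless_kept(self):
        gps, presence = self.setup_pairs()
        g = com.export_cluster_network(["d1"], gps, presence, edge_min_aggregate=100.0)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 0
        g2 = com.export_cluster_network(
            ["d1"], gps, presence, edge_min_aggregate=100.0, keep_isolated=True
        )
        assert g2.number_of_nodes() == 6

    def test_single_edge_weight(self):
        gps, presence = self.setup_pairs()
        g = com.export_cluster_network(["d1"], gps[:1], presence, edge_min_aggregate=15.0)
        assert g.edges["G1", "G2"]["weight"] == pytest.approx(20.0)

    def test_node_weight_is_incident_sum(self, rng):
        # star around G0 plus an extra edge; brute-force incidence sums
        gps = []
        for i in range(1, 6):
            gp = com.GenusPair("G0", f"G{i}")
            gp.supporting_ko_pairs.append(("K00001", "K00002"))
            gp.supporter_scores.append(float(rng.uniform(1, 30)))
            gps.append(gp)
        keys = [g.key for g in gps]
        presence = com.DonorPresenceMatrix(["d1"], keys, np.ones((1, len(keys)), dtype=int))
        g = com.export_cluster_network(["d1"], gps, presence, edge_min_aggregate=10.0)
        for node in g.nodes:
            expected = sum(
                gp.aggregate_score
                for gp in gps
                if node in gp.key and gp.aggregate_score >= 10.0
            )
            assert g.nodes[node]["weight"] == pytest.approx(expected)

    def test_pair_absent_from_cluster_donors_excluded(self):
        gps, presence = self.setup_pairs()
        presence.matrix[0, 0] = 0  # (G1,G2) absent in d1
        g = com.export_cluster_network(["d1"], gps, presence, edge_min_aggregate=1.0)
        assert ("G1", "G2") not in {tuple(sorted(e)) for e in g.edges}


def test_newick_export_parses_and_keeps_leaves(tmp_path):
    import dendropy

    m = com.DonorPresenceMatrix(
        [f"d{i}" for i in range(5)],
        [(f"Ga{j}", f"Gb{j}") for j in range(4)],
        np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1], [1, 0, 1, 0]]
        ),
    )
    cl = com.cluster_donors(m, n_clusters=2)
    newick = com.dendrogram_newick(cl)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(m.donors)


def test_graphml_round_trip(tmp_path):
    import networkx as nx

    gp = com.GenusPair("G1", "G2")
    gp.supporting_ko_pairs.append(("K00001", "K00002"))
    gp.supporter_scores.append(20.0)
    presence = com.DonorPresenceMatrix(["d1"], [gp.key], np.ones((1, 1), dtype=int))
    g = com.export_cluster_network(["d1"], [gp], presence, edge_min_aggregate=1.0)
    path = tmp_path / "net.graphml"
    com.write_network_graphml(g, path)
    again = nx.read_graphml(path)
    assert set(again.nodes) == set(g.nodes)
    assert again.edges["G1", "G2"]["weight"] == pytest.approx(20.0)
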