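"""Interactome cleaning, disease-network extraction, overlap algebra,
and guilt-by-association candidate ranking."""

import numpy as np
import pytest

from comorbnet.genesets import GeneRecord, GeneSet, merge_gene_sets
from comorbnet.network import (
    CandidateNotInNetworkError,
    EdgeListError,
    Interactome,
    UBIQUITIN_GENES,
    extract_candidate_neighborhood,
    extract_disease_network,
    intersect_networks,
    merge_interactomes,
    predict_candidates,
    read_edge_list,
    shared_gene_neighbor_count,
    union_networks,
    write_edge_list,
)


def gene_set(label, ids):
    return GeneSet(label, [GeneRecord(g) for g in ids])


def net_from(pairs):
    return Interactome.from_edges(pairs)


def random_interactome(rng, n_nodes=40, n_edges=60):
    pairs = zip(rng.integers(1, n_nodes + 1, n_edges),
                rng.integers(1, n_nodes + 1, n_edges))
    return net_from(list(pairs))


class TestInteractome:
    def test_reversed_and_self_pairs_collapse(self):
        net = net_from([(1, 2), (2, 1), (3, 3)])
        assert net.edges == {(1, 2)}

    def test_nodes_are_edge_endpoints_only(self):
        net = net_from([(5, 9), (2, 9)])
        assert net.nodes == {2, 5, 9}

    def test_self_loop_rejected_by_constructor(self):
        with pytest.raises(ValueError):
            Interactome(frozenset({(4, 4)}))

    def test_noncanonical_edge_rejected_by_constructor(self):
        with pytest.raises(ValueError):
            Interactome(frozenset({(5, 2)}))

    def test_degree_counts_neighbors(self):
        net = net_from([(1, 2), (1, 3), (2, 3)])
        assert net.degree() == {1: 2, 2: 2, 3: 2}


class TestReadEdgeList:
    def test_dedup_and_self_pair_drop(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("1\t2\n2\t1\n3\t3\n")
        net = read_edge_list(path)
        assert net.edges == {(1, 2)}

    def test_empty_file_gives_empty_interactome(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        assert read_edge_list(path).n_edges == 0

    def test_three_distinct_rows_three_edges(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("1\t2\n3\t4\n5\t6\n")
        assert read_edge_list(path).n_edges == 3

    def test_header_row_auto_detected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene_a\tgene_b\n1\t2\n")
        assert read_edge_list(path).edges == {(1, 2)}

    def test_non_integer_id_in_body_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("1\t2\nfoo\t3\n")
        with pytest.raises(EdgeListError):
            read_edge_list(path)

    def test_single_column_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("1\n")
        with pytest.raises(EdgeListError):
            read_edge_list(path)

    def test_write_read_round_trip(self, tmp_path):
        net = net_from([(1, 2), (4, 3), (9, 2)])
        write_edge_list(net, tmp_path / "e.tsv")
        assert read_edge_list(tmp_path / "e.tsv").edges == net.edges


class TestMergeInteractomes:
    def test_union_deduplicates(self):
        merged = merge_interactomes(
            [net_from([(1, 2)]), net_from([(1, 2), (2, 3)])], exclude=frozenset()
        )
        assert merged.n_edges == 2

    def test_excluded_gene_edges_removed(self):
        merged = merge_interactomes([net_from([(7316, 5), (5, 6)])])
        assert merged.edges == {(5, 6)}
        assert not merged.nodes & UBIQUITIN_GENES

    def test_default_exclusion_is_the_three_ubiquitin_genes(self):
        assert UBIQUITIN_GENES == {7316, 7314, 10537}


class TestExtraction:
    path_net = net_from([(1, 2), (2, 3)])  # path a-b-c

    def test_edge_incident_keeps_edges_touching_seeds(self):
        dn = extract_disease_network(self.path_net, gene_set("d", [2]))
        assert dn.network.n_edges == 2 and dn.network.n_nodes == 3

    def test_induced_rule_requires_both_endpoints(self):
        dn = extract_disease_network(self.path_net, gene_set("d", [1, 2]),
                                     rule="induced")
        assert dn.network.edges == {(1, 2)}

    def test_seeds_without_incident_edges_yield_empty_network(self):
        dn = extract_disease_network(self.path_net, gene_set("d", [99]))
        assert dn.network.n_edges == 0

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            extract_disease_network(self.path_net, gene_set("d", []))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            extract_disease_network(self.path_net, gene_set("d", [1]), rule="fuzzy")


class TestNetworkAlgebra:
    def test_union_of_identical_networks_is_identity(self):
        dn = extract_disease_network(net_from([(1, 2), (2, 3)]), gene_set("d", [2]))
        assert union_networks(dn, dn).edges == dn.network.edges

    def test_union_of_disjoint_edge_sets_sums_counts(self):
        a = extract_disease_network(net_from([(1, 2)]), gene_set("a", [1]))
        b = extract_disease_network(net_from([(5, 6)]), gene_set("b", [5]))
        assert union_networks(a, b).n_edges == 2

    def test_intersection_nodes_are_common_edge_endpoints(self):
        a = extract_disease_network(net_from([(1, 2), (2, 3)]), gene_set("a", [1, 2, 3]))
        b = extract_disease_network(net_from([(2, 3), (3, 4)]), gene_set("b", [2, 3, 4]))
        overlap = intersect_networks(a, b)
        assert overlap.edges == {(2, 3)}
        assert overlap.nodes == {2, 3}

    def test_inclusion_exclusion_and_subset_chain_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            source = random_interactome(rng)
            nodes = sorted(source.nodes)
            seeds_a = gene_set("a", rng.choice(nodes, size=6, replace=False))
            seeds_b = gene_set("b", rng.choice(nodes, size=6, replace=False))
            a = extract_disease_network(source, seeds_a)
            b = extract_disease_network(source, seeds_b)
            union = union_networks(a, b)
            overlap = intersect_networks(a, b)
            assert a.network.n_edges + b.network.n_edges == union.n_edges + overlap.n_edges
            assert overlap.edges <= a.network.edges <= union.edges <= source.edges

    def test_every_nonseed_overlap_node_touches_a_shared_seed(self, small_dataset):
        """Under edge-incident extraction, an overlap-network node outside
        both seed sets can only be reached through a gene in both seed
        sets, so its overlap degree equals its shared-gene neighbor count."""
        ds = small_dataset
        a = extract_disease_network(ds.interactome, ds.genes_a)
        b = extract_disease_network(ds.interactome, ds.genes_b)
        overlap = intersect_networks(a, b)
        shared = ds.shared_gene_ids
        disease = ds.genes_a.gene_ids | ds.genes_b.gene_ids
        counts = shared_gene_neighbor_count(overlap, shared)
        degree = overlap.degree()
        non_disease = [n for n in overlap.nodes if n not in disease]
        assert non_disease, "fixture should produce non-disease overlap nodes"
        for node in non_disease:
            assert counts[node] >= 1
            assert counts[node] == degree[node]


class TestSharedNeighborCounts:
    def test_star_center_counts_all_shared_leaves(self):
        star = net_from([(10, 1), (10, 2), (10, 3), (10, 4)])
        counts = shared_gene_neighbor_count(star, {1, 2, 3, 4})
        assert counts[10] == 4

    def test_node_without_shared_neighbors_scores_zero(self):
        net = net_from([(1, 2), (3, 4)])
        counts = shared_gene_neighbor_count(net, {1})
        assert counts[3] == 0 and counts[4] == 0

    def test_shared_genes_themselves_are_scored(self):
        net = net_from([(1, 2)])
        counts = shared_gene_neighbor_count(net, {1, 2})
        assert counts[1] == 1 and counts[2] == 1


class TestPredictCandidates:
    def test_known_genes_are_excluded_from_novel_calls(self):
        counts = {1: 9, 2: 7, 3: 6}
        ranking = predict_candidates(counts, gene_set("k", [1, 2, 3]), 6)
        assert ranking.novel == []

    def test_threshold_and_deterministic_ordering(self):
        counts = {5: 7, 3: 7, 9: 10, 4: 2}
        ranking = predict_candidates(counts, gene_set("k", []), 6)
        assert ranking.novel_gene_ids == [9, 3, 5]  # count desc, id asc on ties

    def test_min_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            predict_candidates({}, gene_set("k", []), 0)

    def test_planted_candidates_recovered_exactly(self, small_dataset):
        ds = small_dataset
        a = extract_disease_network(ds.interactome, ds.genes_a)
        b = extract_disease_network(ds.interactome, ds.genes_b)
        overlap = intersect_networks(a, b)
        counts = shared_gene_neighbor_count(overlap, ds.shared_gene_ids)
        known = merge_gene_sets(ds.genes_a, ds.genes_b, "all")
        ranking = predict_candidates(counts, known, ds.config.candidate_wiring)
        assert set(ranking.novel_gene_ids) == set(ds.truth.planted_candidates)


class TestCandidateNeighborhood:
    def test_single_candidate_star(self):
        net = net_from([(10, 1), (10, 2), (10, 3), (1, 2)])
        sub = extract_candidate_neighborhood(net, [10])
        assert sub.network.n_nodes == 4 and sub.network.n_edges == 3
        assert sub.node_classes[10] == "candidate"

    def test_shared_neighbor_appears_once(self):
        net = net_from([(10, 1), (11, 1)])
        sub = extract_candidate_neighborhood(net, [10, 11])
        assert sub.network.n_nodes == 3

    def test_absent_candidate_rejected(self):
        with pytest.raises(CandidateNotInNetworkError):
            extract_candidate_neighborhood(net_from([(1, 2)]), [99])

    def test_annotation_labels_applied(self):
        net = net_from([(10, 1), (10, 2)])
        sub = extract_candidate_neighborhood(net, [10],
                                             annot={"a": {1}, "shared": {2}})
        assert sub.node_classes == {10: "candidate", 1: "a", 2: "shared"}
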