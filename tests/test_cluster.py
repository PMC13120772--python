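"""Greedy set-cover clustering, size filter and neighbourhood merging."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ghannot.cluster import (
    ClusteringConfig,
    GreedySetCoverClustering,
    LocusNeighbourhood,
    deduplicate_loci,
    extract_neighbourhoods,
    filter_min_size,
    greedy_cluster,
    merge_by_neighbourhood,
)
from ghannot.align import align_pair
from ghannot.io import ReferenceSequence
from ghannot.synthetic import mutate_to_identity, random_sequence


def _planted_family(rng, n_groups=3, per_group=10, length=150, to_centroid=93.0):
    """Groups with within-group identity >= ~85% and unrelated between groups."""
    seqs = []
    truth = {}
    for g in range(n_groups):
        centroid = random_sequence(length, rng)
        for m in range(per_group):
            seq = mutate_to_identity(centroid, to_centroid, rng)
            sid = f"g{g}_m{m:02d}"
            seqs.append(ReferenceSequence(sid, f"gen{m}", "GH2", seq))
            truth[sid] = g
    return seqs, truth


def _components_oracle(seqs, min_seq_id, coverage):
    """Connected components of the thresholded identity graph (networkx)."""
    graph = nx.Graph()
    graph.add_nodes_from(s.seq_id for s in seqs)
    for a, b in itertools.combinations(seqs, 2):
        hit = align_pair(a.sequence, b.sequence)
        if (
            hit is not None
            and hit.percent_identity >= 100 * min_seq_id
            and hit.query_coverage >= coverage
        ):
            graph.add_edge(a.seq_id, b.seq_id)
    return [frozenset(c) for c in nx.connected_components(graph)]


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self, rng):
        seq = random_sequence(80, rng)
        seqs = [ReferenceSequence(f"s{i}", "g", "GH2", seq) for i in range(3)]
        clusters = greedy_cluster(seqs)
        assert len(clusters) == 1
        assert sorted(next(iter(clusters.values()))) == ["s0", "s1", "s2"]

    def test_distant_pair_stays_singletons(self, rng):
        a = random_sequence(100, rng)
        b = mutate_to_identity(a, 40.0, rng)
        clusters = greedy_cluster(
            [ReferenceSequence("a", "g", "GH2", a), ReferenceSequence("b", "g", "GH2", b)]
        )
        assert len(clusters) == 2

    def test_recovers_planted_partition_vs_components_oracle(self):
        rng = np.random.default_rng(99)
        seqs, truth = _planted_family(rng)
        config = ClusteringConfig(min_seq_id=0.70, coverage=0.80)
        clusters = greedy_cluster(seqs, config)
        got = {frozenset(m) for m in clusters.values()}
        oracle = set(_components_oracle(seqs, 0.70, 0.80))
        assert got == oracle
        assert len(got) == 3
        for members in got:  # each recovered cluster is one planted group
            assert len({truth[sid] for sid in members}) == 1

    def test_output_is_partition_and_members_cover_centroid(self, rng):
        seqs, _ = _planted_family(rng, n_groups=2, per_group=5, length=100)
        config = ClusteringConfig(min_seq_id=0.70, coverage=0.80)
        clusters = greedy_cluster(seqs, config)
        all_members = [m for ms in clusters.values() for m in ms]
        assert sorted(all_members) == sorted(s.seq_id for s in seqs)
        by_id = {s.seq_id: s for s in seqs}
        for cid, members in clusters.items():
            for m in members:
                hit = align_pair(by_id[m].sequence, by_id[cid].sequence)
                assert hit.percent_identity >= 70.0
                assert hit.query_coverage >= 0.80

    def test_empty_input_gives_empty_map(self):
        assert greedy_cluster([]) == {}

    def test_multiple_families_rejected(self, rng):
        seqs = [
            ReferenceSequence("a", "g", "GH2", random_sequence(60, rng)),
            ReferenceSequence("b", "g", "GH95", random_sequence(60, rng)),
        ]
        with pytest.raises(ValueError, match="one family"):
            greedy_cluster(seqs)

    def test_estimator_labels_match_cluster_map(self, rng):
        seqs, _ = _planted_family(rng, n_groups=2, per_group=4, length=100)
        est = GreedySetCoverClustering(min_seq_id=0.70, coverage=0.80)
        labels = est.fit_predict(seqs)
        assert len(labels) == len(seqs)
        assert len(set(labels)) == len(est.clusters_)
        assert est.get_params()["min_seq_id"] == 0.70


class TestFilterMinSize:
    @pytest.mark.parametrize(
        "threshold,retained_ids",
        [(5, {"a", "c"}), (1, {"a", "b", "c"}), (10, set())],
    )
    def test_partition_by_size(self, threshold, retained_ids):
        clusters = {"a": ["x"] * 5, "b": ["x"] * 4, "c": ["x"] * 6}
        retained, removed = filter_min_size(clusters, threshold)
        assert set(retained) == retained_ids
        assert set(retained) | set(removed) == set(clusters)
        total = sum(map(len, clusters.values()))
        assert sum(map(len, retained.values())) + sum(map(len, removed.values())) == total


def _locus(lid, genome, cluster, genes, family="GH2"):
    return LocusNeighbourhood(lid, genome, f"{cluster}_anchor", cluster,
                              frozenset(genes), family)


class TestDeduplicateLoci:
    def test_same_locus_from_two_seeds_collapses(self):
        loci = [
            _locus("ctg1:10-20", "g1", "c1", {"a"}),
            _locus("ctg1:10-20", "g1", "c2", {"a"}),
        ]
        out = deduplicate_loci(loci)
        assert len(out) == 1
        assert out[0].anchor_cluster_id == "c1"  # first by input order

    def test_distinct_loci_unchanged(self):
        loci = [_locus(f"ctg1:{i}-{i+9}", "g1", "c1", {"a"}) for i in range(0, 100, 10)]
        assert deduplicate_loci(loci) == loci

    def test_planted_duplicates_removed(self):
        loci = [_locus(f"ctg1:{i}-{i+9}", "g1", "c1", {"a"}) for i in range(0, 70, 10)]
        loci += loci[:3]
        assert len(deduplicate_loci(loci)) == 7


class TestMergeByNeighbourhood:
    def test_identical_gene_content_merges(self):
        loci = [_locus("l1", "g1", "c1", {"a", "b"}), _locus("l2", "g2", "c2", {"a", "b"})]
        mapping = merge_by_neighbourhood(loci)
        assert mapping == {"c1": "c1", "c2": "c1"}

    def test_difference_of_three_does_not_merge(self):
        loci = [_locus("l1", "g1", "c1", {"a", "b", "c"}),
                _locus("l2", "g2", "c2", {"a", "d", "e"})]
        mapping = merge_by_neighbourhood(loci, max_gene_diff=2)
        assert mapping == {"c1": "c1", "c2": "c2"}

    def test_brute_force_oracle_on_planted_family(self):
        # clusters 1-2 differ by one label, 3-4 by five labels
        loci = [
            _locus("l1", "g1", "c1", {"a", "b", "c"}),
            _locus("l2", "g2", "c2", {"a", "b", "c", "d"}),
            _locus("l3", "g3", "c3", {"p", "q", "r"}),
            _locus("l4", "g4", "c4", {"v", "w", "x", "y", "z", "p"}),
        ]
        mapping = merge_by_neighbourhood(loci, max_gene_diff=2)
        assert len(set(mapping.values())) == 3
        # brute-force pairwise symmetric difference + union-find oracle
        graph = nx.Graph()
        graph.add_nodes_from(l.anchor_cluster_id for l in loci)
        for a, b in itertools.combinations(loci, 2):
            if len(a.gene_content ^ b.gene_content) <= 2:
                graph.add_edge(a.anchor_cluster_id, b.anchor_cluster_id)
        oracle = {frozenset(c) for c in nx.connected_components(graph)}
        got = {}
        for old, new in mapping.items():
            got.setdefault(new, set()).add(old)
        assert {frozenset(v) for v in got.values()} == oracle

    def test_merge_is_transitive_and_keeps_smallest_id(self):
        loci = [
            _locus("l1", "g1", "c3", {"a", "b"}),
            _locus("l2", "g2", "c2", {"a", "b", "c"}),
            _locus("l3", "g3", "c1", {"a", "b", "c", "d"}),
        ]
        mapping = merge_by_neighbourhood(loci, max_gene_diff=2)
        assert set(mapping.values()) == {"c1"}

    def test_idempotent_and_never_increases_cluster_count(self):
        rng = np.random.default_rng(5)
        labels = [f"gene{i}" for i in range(12)]
        loci = [
            _locus(f"l{i}", f"g{i}", f"c{i}",
                   set(rng.choice(labels, size=5, replace=False)))
            for i in range(8)
        ]
        mapping = merge_by_neighbourhood(loci)
        assert len(set(mapping.values())) <= len({l.anchor_cluster_id for l in loci})
        # idempotent: relabel anchors by merged id and merge again
        relabelled = [
            LocusNeighbourhood(l.locus_id, l.genome_id, l.anchor_seq_id,
                               mapping[l.anchor_cluster_id], l.gene_content, l.family)
            for l in loci
        ]
        second = merge_by_neighbourhood(relabelled)
        assert all(second[c] == c for c in set(mapping.values()))

    def test_function_groups_block_merging(self):
        loci = [_locus("l1", "g1", "c1", {"a", "b"}), _locus("l2", "g2", "c2", {"a", "b"})]
        mapping = merge_by_neighbourhood(
            loci, function_groups={"c1": "fucosidase", "c2": "sialidase"}
        )
        assert mapping == {"c1": "c1", "c2": "c2"}

    def test_multi_family_loci_rejected(self):
        loci = [_locus("l1", "g1", "c1", {"a"}, family="GH2"),
                _locus("l2", "g2", "c2", {"a"}, family="GH95")]
        with pytest.raises(ValueError, match="famil"):
            merge_by_neighbourhood(loci)


class TestExtractNeighbourhoods:
    def test_window_and_anchor_exclusion(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "genome_id": ["g1"] * 4,
                "contig_id": ["ctg1"] * 4,
                "gene_id": ["anchor", "near", "far", "other_label"],
                "orthologue_label": ["GHX", "permease", "kinase", "GHX"],
                "start": [50_000, 60_000, 90_000, 55_000],
                "end": [51_000, 61_000, 91_000, 56_000],
                "strand": [1, 1, 1, -1],
            }
        )
        loci = extract_neighbourhoods(table, {"anchor": ("c1", "GH2")}, window=20_000)
        assert len(loci) == 1
        # 'far' is outside the 20 kb window; the anchor's own label is excluded
        assert loci[0].gene_content == frozenset({"permease"})
        assert loci[0].genome_id == "g1"
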