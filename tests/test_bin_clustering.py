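import numpy as np
import pytest
from conftest import make_matrix, make_records

from barcodegap import (
    ClusterAssignment,
    RESLConfig,
    SequenceDataset,
    assign_bins,
    concordance,
    mcl_refine,
    silhouette_mean,
    single_linkage_preclusters,
)


class TestPreclusters:
    def test_two_separated_groups(self):
        ids = ["a", "b", "x", "y"]
        m = make_matrix(ids, {("a", "b"): 0.5, ("x", "y"): 0.5,
                              ("a", "x"): 5.0, ("a", "y"): 5.0,
                              ("b", "x"): 5.0, ("b", "y"): 5.0})
        pre = single_linkage_preclusters(m, 2.2)
        assert pre.n_clusters == 2

    def test_chaining(self):
        # A-B 2.0, B-C 2.0, A-C 4.0: one cluster through the chain
        ids = ["A", "B", "C"]
        m = make_matrix(ids, {("A", "B"): 2.0, ("B", "C"): 2.0, ("A", "C"): 4.0})
        pre = single_linkage_preclusters(m, 2.2)
        assert pre.n_clusters == 1

    def test_all_far_apart_gives_singletons(self):
        ids = ["A", "B", "C"]
        m = make_matrix(ids, {("A", "B"): 3.0, ("B", "C"): 3.0, ("A", "C"): 3.0})
        pre = single_linkage_preclusters(m, 2.2)
        assert pre.n_clusters == 3

    def test_undefined_pairs_contribute_no_edge(self):
        ids = ["A", "B"]
        m = make_matrix(ids, {("A", "B"): 1.0})
        m.d[0, 1] = m.d[1, 0] = np.nan
        assert single_linkage_preclusters(m, 2.2).n_clusters == 2


class TestMCLRefine:
    def _two_clumps(self):
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        ent = {}
        for i in range(8):
            for j in range(i + 1, 8):
                same = (i < 4) == (j < 4)
                ent[(ids[i], ids[j])] = 0.3 if same else 2.0
        return ids, make_matrix(ids, ent)

    def test_two_tight_clumps_split(self):
        ids, m = self._two_clumps()
        labels, ok = mcl_refine(ids, m, RESLConfig())
        assert ok
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        # the split is also the exhaustive silhouette optimum over 2-partitions
        best = max(
            (silhouette_mean(np.array([int(i in grp) for i in range(8)]), m.d)
             for grp in _nontrivial_subsets(8)),
            default=0.0,
        )
        assert silhouette_mean(labels, m.d) == pytest.approx(best)

    def test_uniform_clump_stays_whole(self):
        ids = [f"a{i}" for i in range(5)]
        ent = {(ids[i], ids[j]): 0.2 for i in range(5) for j in range(i + 1, 5)}
        m = make_matrix(ids, ent)
        labels, ok = mcl_refine(ids, m, RESLConfig())
        assert ok and len(np.unique(labels)) == 1

    def test_size_two_never_errors(self):
        ids = ["a", "b"]
        m = make_matrix(ids, {("a", "b"): 1.0})
        labels, ok = mcl_refine(ids, m, RESLConfig())
        assert len(labels) == 2


def _nontrivial_subsets(n):
    for mask in range(1, 2 ** (n - 1)):
        yield {i for i in range(n) if mask >> i & 1}


class TestSilhouette:
    def test_hand_computed_point(self):
        # 3 points: i with a(i)=1 to its own partner, b(i)=3 to the other
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        labels = np.array([0, 0, 1])
        # s(0)=s(1)=(3-1)/3, s(2)=0 (singleton)
        assert silhouette_mean(labels, d) == pytest.approx((2 / 3 + 2 / 3 + 0) / 3)

    def test_a_equals_b_is_zero(self):
        d = np.array([[0.0, 2.0, 2.0], [2.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        # two clusters, every between/within distance equal
        assert silhouette_mean(np.array([0, 0, 1]), d) == pytest.approx(0.0)

    def test_single_cluster_defined_as_zero(self):
        d = np.zeros((3, 3))
        assert silhouette_mean(np.array([0, 0, 0]), d) == 0.0

    def test_well_separated_near_one(self):
        ids = [f"s{i}" for i in range(6)]
        ent = {}
        for i in range(6):
            for j in range(i + 1, 6):
                same = (i < 3) == (j < 3)
                ent[(ids[i], ids[j])] = 0.05 if same else 8.0
        m = make_matrix(ids, ent)
        assert silhouette_mean(np.array([0, 0, 0, 1, 1, 1]), m.d) > 0.95


class TestAssignBins:
    def test_deep_split_species_yields_two_clusters(self):
        # one species with a 4% split, neighbour at 8%
        ids = ["a1", "a2", "b1", "b2", "x"]
        ent = {("a1", "a2"): 0.2, ("b1", "b2"): 0.2}
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                ent[(a, b)] = 4.0
        for s in ("a1", "a2", "b1", "b2"):
            ent[(s, "x")] = 8.0
        m = make_matrix(ids, ent)
        ds = SequenceDataset(records=make_records(
            [("a1", "G sp1", "reference"), ("a2", "G sp1", "reference"),
             ("b1", "G sp1", "query"), ("b2", "G sp1", "query"),
             ("x", "G sp2", "reference")]))
        assignment = assign_bins(m, ds)
        sp1_clusters = {assignment.specimen_to_cluster[s] for s in ("a1", "a2", "b1", "b2")}
        assert len(sp1_clusters) == 2

    def test_refinement_never_merges_preclusters(self, paper_like, paper_like_matrix):
        ds, _ = paper_like
        cfg = RESLConfig()
        pre = single_linkage_preclusters(paper_like_matrix, cfg.precluster_threshold)
        fine = assign_bins(paper_like_matrix, ds, cfg)
        pre_of = pre.specimen_to_cluster
        fine_to_pre = {}
        for sid, c in fine.specimen_to_cluster.items():
            fine_to_pre.setdefault(c, set()).add(pre_of[sid])
        assert all(len(v) == 1 for v in fine_to_pre.values())

    def test_input_order_permutation_preserves_partition(self, paper_like):
        from barcodegap import pairwise_matrix

        ds, _ = paper_like
        sub = SequenceDataset(records=ds.records[:120], alignment_length=ds.alignment_length)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(sub.records)))
        shuffled = SequenceDataset(
            records=[sub.records[i] for i in perm], alignment_length=sub.alignment_length
        )
        a1 = assign_bins(pairwise_matrix(sub), sub)
        a2 = assign_bins(pairwise_matrix(shuffled), shuffled)
        part1 = {frozenset(v) for v in a1.clusters.values()}
        part2 = {frozenset(v) for v in a2.clusters.values()}
        assert part1 == part2


class TestConcordance:
    def test_all_four_classes_on_toy_set(self):
        # match: spM alone in one cluster
        # merge: spA+spB pooled in one cluster
        # split: spS in two clusters, none shared
        # mixture: spX in two clusters, one shared with spY (spY -> merge)
        ds = SequenceDataset(records=make_records([
            ("m1", "G spM", "reference"),
            ("a1", "G spA", "reference"), ("b1", "G spB", "reference"),
            ("s1", "G spS", "reference"), ("s2", "G spS", "query"),
            ("x1", "G spX", "reference"), ("x2", "G spX", "query"),
            ("y1", "G spY", "query"),
        ]))
        assignment = ClusterAssignment(
            specimen_to_cluster={
                "m1": "C1", "a1": "C2", "b1": "C2",
                "s1": "C3", "s2": "C4",
                "x1": "C5", "x2": "C6", "y1": "C6",
            },
            clusters={"C1": ["m1"], "C2": ["a1", "b1"], "C3": ["s1"],
                      "C4": ["s2"], "C5": ["x1"], "C6": ["x2", "y1"]},
        )
        records, agg = concordance(assignment, ds)
        cls = {r.species: r.concordance_class for r in records}
        assert cls == {"G spM": "match", "G spA": "merge", "G spB": "merge",
                       "G spS": "split", "G spX": "mixture", "G spY": "merge"}
        split = next(r for r in records if r.species == "G spS")
        assert split.split_regional_pattern == "between_regions"
        assert agg["by_class"] == {"match": 1, "merge": 3, "split": 1, "mixture": 1}

    def test_within_region_split_pattern(self):
        ds = SequenceDataset(records=make_records([
            ("s1", "G spS", "reference"), ("s2", "G spS", "reference"),
        ]))
        assignment = ClusterAssignment(
            specimen_to_cluster={"s1": "C1", "s2": "C2"},
            clusters={"C1": ["s1"], "C2": ["s2"]},
        )
        records, _ = concordance(assignment, ds)
        assert records[0].split_regional_pattern == "within_region"
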