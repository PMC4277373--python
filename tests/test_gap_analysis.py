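import math

import numpy as np
import pytest
from conftest import make_matrix, make_records

from barcodegap import (
    SequenceDataset,
    diagnosable,
    harmonic_mean,
    intra_vs_samplesize_residuals,
    nn_vs_samplesize_regression,
    partition_compare,
    species_stats,
    threshold_census,
)


def brute_force_species_stats(m, ds):
    """Exhaustive double-loop recomputation of the per-species statistics."""
    sp_of = {r.specimen_id: r.species for r in ds.records}
    species = sorted({r.species for r in ds.records})
    out = {}
    for sp in species:
        own = [s for s in m.ids if sp_of[s] == sp]
        intra = []
        for i, a in enumerate(own):
            for b in own[i + 1:]:
                v = m.d[m.index_of(a), m.index_of(b)]
                if not math.isnan(v):
                    intra.append(v)
        nn_sp, nn = None, float("nan")
        for other in species:
            if other == sp:
                continue
            vals = [
                m.d[m.index_of(a), m.index_of(b)]
                for a in own
                for b in m.ids
                if sp_of[b] == other
                and not math.isnan(m.d[m.index_of(a), m.index_of(b)])
            ]
            if not vals:
                continue
            v = min(vals) * 100.0
            if math.isnan(nn) or v < nn:
                nn_sp, nn = other, v
        out[sp] = {
            "n": len(own),
            "max_intra": max(intra) * 100.0 if intra else 0.0,
            "mean_intra": float(np.mean(intra)) * 100.0 if intra else 0.0,
            "nn_species": nn_sp,
            "nn_dist": nn,
        }
    return out


def _random_dataset(seed, n=20, length=658):
    """Random specimens spread over a handful of species with varied divergence."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=length)
    seqs, rows = [], []
    n_species = 6
    anc = {}
    for s in range(n_species):
        a = base.copy()
        sites = rng.choice(length, size=rng.integers(10, 60), replace=False)
        a[sites] = (a[sites] + rng.integers(1, 4, size=len(sites))) % 4
        anc[s] = a
    for i in range(n):
        s = int(rng.integers(0, n_species))
        seq = anc[s].copy()
        sites = rng.choice(length, size=rng.integers(0, 12), replace=False)
        seq[sites] = (seq[sites] + rng.integers(1, 4, size=len(sites))) % 4
        seq_str = "".join("ACGT"[c] for c in seq)
        role = "reference" if rng.random() < 0.7 else "query"
        rows.append((f"s{i}", f"Genus sp{s}", role, seq_str))
    return SequenceDataset(records=make_records(rows, seq_length=length))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_species_stats_match_brute_force(seed):
    from barcodegap import pairwise_matrix

    ds = _random_dataset(seed)
    m = pairwise_matrix(ds)
    expected = brute_force_species_stats(m, ds)
    for s in species_stats(m, ds):
        e = expected[s.species]
        assert s.n_specimens == e["n"]
        assert s.max_intra == e["max_intra"]
        assert s.mean_intra == e["mean_intra"]
        assert s.nn_species == e["nn_species"]
        assert (math.isnan(s.nn_dist) and math.isnan(e["nn_dist"])) or s.nn_dist == e["nn_dist"]


def test_species_stats_toy_example():
    # sp1: three specimens with pairwise {1.0, 2.0, 1.5}%; sp2 at >=5.0%
    ids = ["a", "b", "c", "x"]
    m = make_matrix(
        ids,
        {("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 1.5,
         ("a", "x"): 5.0, ("b", "x"): 6.0, ("c", "x"): 5.5},
    )
    ds = SequenceDataset(records=make_records(
        [("a", "G sp1", "reference"), ("b", "G sp1", "reference"),
         ("c", "G sp1", "reference"), ("x", "G sp2", "reference")]))
    stats = {s.species: s for s in species_stats(m, ds)}
    s1 = stats["G sp1"]
    assert s1.max_intra == pytest.approx(2.0)
    assert s1.mean_intra == pytest.approx(1.5)
    assert s1.nn_species == "G sp2"
    assert s1.nn_dist == pytest.approx(5.0)
    assert s1.gap_present
    s2 = stats["G sp2"]
    assert s2.singleton and s2.max_intra == 0.0
    assert s2.harmonic_n == pytest.approx(harmonic_mean(1, 3))


def test_shared_barcode_has_no_gap():
    ids = ["a", "x"]
    m = make_matrix(ids, {("a", "x"): 0.0})
    ds = SequenceDataset(records=make_records(
        [("a", "G sp1", "reference"), ("x", "G sp2", "reference")]))
    stats = {s.species: s for s in species_stats(m, ds)}
    assert stats["G sp1"].nn_dist == 0.0
    assert not stats["G sp1"].gap_present
    assert not stats["G sp1"].diagnosable


class TestDiagnosable:
    def test_deep_split_still_diagnosable(self):
        # intra chain max edge 4% but NN at 7%: single linkage isolates it
        ids = ["a", "b", "x"]
        m = make_matrix(ids, {("a", "b"): 4.0, ("a", "x"): 7.0, ("b", "x"): 8.0})
        ds = SequenceDataset(records=make_records(
            [("a", "G sp1", "reference"), ("b", "G sp1", "reference"),
             ("x", "G sp2", "reference")]))
        assert diagnosable("G sp1", m, ds)

    def test_intermingled_species_not_diagnosable(self):
        # sp1 specimens are farther from each other than from sp2
        ids = ["a", "b", "x"]
        m = make_matrix(ids, {("a", "b"): 5.0, ("a", "x"): 1.0, ("b", "x"): 5.5})
        ds = SequenceDataset(records=make_records(
            [("a", "G sp1", "reference"), ("b", "G sp1", "reference"),
             ("x", "G sp2", "reference")]))
        assert not diagnosable("G sp1", m, ds)

    def test_separated_species_both_diagnosable(self):
        ids = ["a", "b", "x", "y"]
        m = make_matrix(ids, {("a", "b"): 0.5, ("x", "y"): 0.4,
                              ("a", "x"): 6.0, ("a", "y"): 6.5,
                              ("b", "x"): 6.2, ("b", "y"): 7.0})
        ds = SequenceDataset(records=make_records(
            [("a", "G sp1", "reference"), ("b", "G sp1", "reference"),
             ("x", "G sp2", "reference"), ("y", "G sp2", "reference")]))
        assert diagnosable("G sp1", m, ds)
        assert diagnosable("G sp2", m, ds)


def test_threshold_census_counts():
    class S:
        def __init__(self, v):
            self.max_intra = v

    stats = [S(0.0), S(0.5), S(1.5), S(3.0)]
    c = threshold_census(stats, [1.0, 2.0])
    assert c["lt_1"] == 2 and c["lt_2"] == 3
    assert c["zero_divergence"] == 1 and c["ge_2"] == 1

    # strict inequality: a species exactly at the threshold is not below it
    c2 = threshold_census([S(1.0)], [1.0])
    assert c2["lt_1"] == 0

    c3 = threshold_census([], [1.0, 2.0])
    assert c3["n_species"] == 0 and c3["lt_1"] == 0


def test_harmonic_mean_values():
    assert harmonic_mean(4, 4) == 4.0
    assert harmonic_mean(1, 3) == 1.5
    assert harmonic_mean(1, 1) == 1.0
    with pytest.raises(ValueError):
        harmonic_mean(0, 3)


class TestRegressions:
    def _stats(self, hs, nns):
        class S:
            def __init__(self, h, nn, i):
                self.harmonic_n = h
                self.nn_dist = nn
                self.n_specimens = int(h)
                self.max_intra = nn
                self.species = f"sp{i}"

        return [S(h, nn, i) for i, (h, nn) in enumerate(zip(hs, nns))]

    def test_exact_line_recovered(self):
        hs = [10 ** x for x in (0.2, 0.5, 1.0, 1.5)]
        nns = [-2 * np.log10(h) + 8 for h in hs]
        slope, intercept, p = nn_vs_samplesize_regression(self._stats(hs, nns))
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert intercept == pytest.approx(8.0, abs=1e-9)
        assert p < 1e-6

    def test_constant_response_gives_zero_slope(self):
        slope, _, _ = nn_vs_samplesize_regression(self._stats([1, 2, 4, 8], [5, 5, 5, 5]))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_normal_equations(self):
        hs = [1, 2, 3, 5, 8]
        nns = [7.0, 6.1, 6.6, 5.2, 4.9]
        x = np.log10(hs)
        beta = np.cov(x, nns, bias=True)[0, 1] / np.var(x)
        slope, _, _ = nn_vs_samplesize_regression(self._stats(hs, nns))
        assert slope == pytest.approx(beta, abs=1e-10)

    def test_residuals_equal_n_fall_back_to_centering(self):
        stats = self._stats([3, 3, 3], [1.0, 2.0, 3.0])
        res = intra_vs_samplesize_residuals(stats)
        assert np.allclose(res.values, [-1.0, 0.0, 1.0])

    def test_residuals_zero_on_perfect_fit(self):
        stats = self._stats([1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
        res = intra_vs_samplesize_residuals(stats)
        assert np.allclose(res.values, 0.0, atol=1e-10)


class TestPartitionCompare:
    def test_pooling_monotonicity_toy(self):
        # query specimen 3% from its reference conspecifics raises the max
        ids = ["r1", "r2", "q1", "o1"]
        m = make_matrix(ids, {("r1", "r2"): 0.5, ("r1", "q1"): 3.0, ("r2", "q1"): 3.2,
                              ("r1", "o1"): 7.0, ("r2", "o1"): 7.5, ("q1", "o1"): 6.0})
        ds = SequenceDataset(records=make_records(
            [("r1", "G sp1", "reference"), ("r2", "G sp1", "reference"),
             ("q1", "G sp1", "query"), ("o1", "G sp2", "reference")]))
        comps = partition_compare(m, ds)
        c = {x.species: x for x in comps}["G sp1"]
        assert c.max_intra_ref == pytest.approx(0.5)
        assert c.max_intra_pooled == pytest.approx(3.2)
        assert c.nn_dist_ref == pytest.approx(7.0)
        assert c.nn_dist_pooled == pytest.approx(6.0)
        assert c.nn_reduction_pct == pytest.approx(100 * (7.0 - 6.0) / 7.0)

    def test_monotonicity_on_simulation(self, paper_like, paper_like_matrix):
        ds, _ = paper_like
        comps = partition_compare(paper_like_matrix, ds)
        assert comps, "no species with reference specimens?"
        for c in comps:
            assert c.max_intra_pooled >= c.max_intra_ref - 1e-12
            if np.isfinite(c.nn_dist_ref) and np.isfinite(c.nn_dist_pooled):
                assert c.nn_dist_pooled <= c.nn_dist_ref + 1e-12
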