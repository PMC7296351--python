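"""Proximity, binning, overlap and permutation-null behaviour."""
import numpy as np
import pytest

from chromaprime.core import GeneRecord, GenomicInterval, SummitPeak
from chromaprime.linkage import (
    closest_tss_assignment,
    distance_bins,
    fraction_within,
    nearest_dhs_distance,
    overlap_venn,
    permutation_enrichment,
    ranked_fc_annotation,
)

from conftest import merge_oracle, random_intervals, random_peaks


def gene(gid, chrom, tss):
    return GeneRecord(gid, chrom, tss, "+", {"T_0": 10.0})


def peak(pid, chrom, summit):
    return SummitPeak(GenomicInterval(chrom, max(0, summit - 200), summit + 200), summit, pid)


class TestClosestTss:
    def test_gene_within_cap_assigned(self):
        assert closest_tss_assignment([peak("p", "chr1", 50000)],
                                      [gene("g", "chr1", 60000)])["p"] == "g"

    def test_gene_beyond_cap_unassigned(self):
        assert closest_tss_assignment([peak("p", "chr1", 50000)],
                                      [gene("g", "chr1", 171000)])["p"] is None

    def test_ties_break_to_smaller_tss_then_gene_id(self):
        genes = [gene("gb", "chr1", 60000), gene("ga", "chr1", 40000)]
        assert closest_tss_assignment([peak("p", "chr1", 50000)], genes)["p"] == "ga"
        genes = [gene("gb", "chr1", 40000), gene("ga", "chr1", 40000)]
        assert closest_tss_assignment([peak("p", "chr1", 50000)], genes)["p"] == "ga"

    def test_matches_exhaustive_oracle(self, rng):
        peaks = random_peaks(rng, 500, max_pos=500000)
        genes = [gene(f"g{i}", ("chr1", "chr2")[int(rng.integers(2))],
                      int(rng.integers(0, 500000))) for i in range(300)]
        got = closest_tss_assignment(peaks, genes, max_dist=100000)
        for p in peaks:
            cands = [
                (abs(p.summit - g.tss), g.tss, g.gene_id)
                for g in genes if g.chrom == p.chrom and abs(p.summit - g.tss) <= 100000
            ]
            assert got[p.peak_id] == (min(cands)[2] if cands else None)


class TestNearestDistance:
    def test_dhs_at_tss_gives_zero(self):
        d = nearest_dhs_distance([gene("g", "chr1", 50000)], [peak("p", "chr1", 50000)])
        assert d["g"] == 0.0

    def test_empty_dhs_set_gives_inf(self):
        d = nearest_dhs_distance([gene("g", "chr1", 50000)], [])
        assert d["g"] == float("inf")

    def test_matches_exhaustive_oracle(self, rng):
        peaks = random_peaks(rng, 300, max_pos=400000)
        genes = [gene(f"g{i}", ("chr1", "chr2")[int(rng.integers(2))],
                      int(rng.integers(0, 400000))) for i in range(200)]
        d = nearest_dhs_distance(genes, peaks)
        for g in genes:
            ds = [abs(g.tss - p.summit) for p in peaks if p.chrom == g.chrom]
            assert d[g.gene_id] == (min(ds) if ds else float("inf"))


class TestFractionWithin:
    def test_colocated_genes_give_one(self):
        genes = [gene(f"g{i}", "chr1", 1000 * (i + 1)) for i in range(5)]
        peaks = [peak(f"p{i}", "chr1", 1000 * (i + 1)) for i in range(5)]
        assert fraction_within(genes, peaks, 0) == 1.0

    def test_zero_distance_with_no_exact_hits(self):
        assert fraction_within([gene("g", "chr1", 500)], [peak("p", "chr1", 600)], 0) == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            fraction_within([], [], 100)

    def test_non_decreasing_in_distance(self, rng):
        peaks = random_peaks(rng, 50, max_pos=300000)
        genes = [gene(f"g{i}", "chr1", int(rng.integers(0, 300000))) for i in range(100)]
        fracs = [fraction_within(genes, peaks, d) for d in (0, 100, 1000, 10000, 100000)]
        assert fracs == sorted(fracs)


class TestDistanceBins:
    def test_single_covering_bin(self):
        genes = [gene("g", "chr1", 1000)]
        out = distance_bins(genes, [peak("p", "chr1", 1500)], [10**9])
        assert out["[0,1000000000)"] == 1.0

    def test_fractions_sum_to_one_and_match_brute_force(self, rng):
        peaks = random_peaks(rng, 40, max_pos=200000)
        genes = [gene(f"g{i}", ("chr1", "chr3")[int(rng.integers(2))],
                      int(rng.integers(0, 200000))) for i in range(120)]
        edges = [1000, 10000, 50000]
        out = distance_bins(genes, peaks, edges)
        assert sum(out.values()) == pytest.approx(1.0)
        d = nearest_dhs_distance(genes, peaks)
        lo = 0
        for hi in edges:
            expect = np.mean([(lo <= v < hi) for v in d.values()])
            assert out[f"[{lo},{hi})"] == pytest.approx(expect)
            lo = hi

    def test_non_monotone_edges_error(self):
        with pytest.raises(ValueError):
            distance_bins([gene("g", "chr1", 1)], [], [100, 100])


class TestOverlapVenn:
    def test_disjoint_sets(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        v = overlap_venn(a, b)
        assert (v.both_a, v.a_only, v.b_only) == (0, 1, 1)

    def test_contained_set_has_no_a_only(self):
        a = [GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 50, 60)]
        b = [GenomicInterval("chr1", 0, 100)]
        v = overlap_venn(a, b)
        assert v.a_only == 0 and v.both_a == 2

    def test_random_sets_match_pairwise_oracle_and_conserve(self, rng):
        a = random_intervals(rng, 400, max_pos=40000)
        b = random_intervals(rng, 300, max_pos=40000)
        v = overlap_venn(a, b, min_overlap=10)
        ma = [GenomicInterval(c, s, e) for c, s, e in merge_oracle(a)]
        mb = [GenomicInterval(c, s, e) for c, s, e in merge_oracle(b)]
        both = sum(
            1 for x in ma
            if any(x.chrom == y.chrom and min(x.end, y.end) - max(x.start, y.start) >= 10
                   for y in mb)
        )
        assert v.both_a == both
        assert v.a_only + v.both_a == len(ma)
        assert v.b_only + v.both_b == len(mb)


class TestPermutationEnrichment:
    def _setup(self, rng, n_universe=400, frac_near=0.1):
        peaks = []
        genes = []
        for i in range(n_universe):
            tss = 200000 * (i + 1)
            genes.append(gene(f"g{i}", "chr1", tss))
            if rng.random() < frac_near:
                peaks.append(peak(f"p{i}", "chr1", tss + int(rng.integers(-40000, 40000))))
        return genes, peaks

    def test_seeded_reproducibility_and_order_invariance(self, rng):
        genes, peaks = self._setup(rng)
        group = genes[:50]
        r1 = permutation_enrichment(group, peaks, genes, 50000, n_perm=200, seed=5)
        r2 = permutation_enrichment(group, peaks, genes, 50000, n_perm=200, seed=5)
        assert r1 == r2
        shuffled = list(genes)[::-1]
        r3 = permutation_enrichment(group, peaks, shuffled, 50000, n_perm=200, seed=5)
        assert r3["observed_fraction"] == r1["observed_fraction"]

    def test_enriched_group_is_significant(self, rng):
        genes, peaks = self._setup(rng, frac_near=0.05)
        # group = genes that actually have a nearby peak (planted enrichment)
        d = nearest_dhs_distance(genes, peaks)
        near = [g for g in genes if d[g.gene_id] <= 50000]
        res = permutation_enrichment(near[:30], peaks, genes, 50000, n_perm=1000, seed=1)
        assert res["p_value"] < 0.01

    def test_low_n_perm_errors(self, rng):
        genes, peaks = self._setup(rng)
        with pytest.raises(ValueError):
            permutation_enrichment(genes[:10], peaks, genes, 50000, n_perm=0)

    def test_group_equal_universe_errors(self, rng):
        genes, peaks = self._setup(rng)
        with pytest.raises(ValueError):
            permutation_enrichment(genes, peaks, genes, 50000, n_perm=200)


class TestRankedFcAnnotation:
    def test_single_pair_and_missing_marker(self):
        p1, p2 = peak("p1", "chr1", 50000), peak("p2", "chr2", 50000)
        genes = [gene("g", "chr1", 60000)]
        out = ranked_fc_annotation([p1, p2], genes, {"g": 2.5})
        assert out == [2.5, None]
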