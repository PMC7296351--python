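"""Union building and differential-DHS classification rules."""
import numpy as np
import pandas as pd
import pytest

from chromaprime.classify import (
    classify_specific,
    count_rate_test,
    exclude_repeats,
    inducible_filter,
    merge_union,
    significant_peaks,
)
from chromaprime.core import GenomicInterval, SummitPeak
from chromaprime.simulate import SimulationParams, simulate

from conftest import bh_oracle, merge_oracle, random_intervals, random_peaks


class TestSignificantPeaks:
    def test_tiny_cutoff_keeps_all_positive(self):
        col = pd.Series([1.0, 5.0, 10.0], index=["a", "b", "c"])
        assert significant_peaks(col, 1e-9) == ["a", "b", "c"]

    def test_cutoff_is_inclusive(self):
        col = pd.Series([1.0, 5.0, 10.0], index=["a", "b", "c"])
        assert significant_peaks(col, 5.0) == ["b", "c"]

    def test_nonpositive_cutoff_errors(self):
        with pytest.raises(ValueError):
            significant_peaks(pd.Series([1.0]), 0.0)


class TestMergeUnion:
    def test_single_set_is_identity(self):
        peaks = [SummitPeak(GenomicInterval("chr1", 0, 100), 50, "a"),
                 SummitPeak(GenomicInterval("chr1", 200, 300), 250, "b")]
        u = merge_union([peaks])
        assert [(p.interval.start, p.interval.end, p.summit) for p in u.peaks] == [
            (0, 100, 50), (200, 300, 250)]

    def test_bookended_intervals_merge(self):
        a = [SummitPeak(GenomicInterval("chr1", 100, 200), 150, "a")]
        b = [SummitPeak(GenomicInterval("chr1", 200, 300), 250, "b")]
        u = merge_union([a, b])
        assert len(u.peaks) == 1
        assert (u.peaks[0].interval.start, u.peaks[0].interval.end) == (100, 300)
        assert sorted(u.provenance[0]) == ["a", "b"]

    def test_representative_summit_takes_highest_count(self):
        a = [SummitPeak(GenomicInterval("chr1", 100, 250), 150, "a")]
        b = [SummitPeak(GenomicInterval("chr1", 200, 300), 250, "b")]
        counts = pd.Series({"a": 5.0, "b": 50.0})
        u = merge_union([a, b], counts)
        assert u.peaks[0].summit == 250
        # tie goes to the smaller coordinate
        u2 = merge_union([a, b], pd.Series({"a": 5.0, "b": 5.0}))
        assert u2.peaks[0].summit == 150

    def test_random_instances_match_pairwise_merge_oracle(self, rng):
        ivs = random_intervals(rng, 1000, max_pos=50000)
        peaks = [SummitPeak(iv, iv.start, f"p{i}") for i, iv in enumerate(ivs)]
        u = merge_union([peaks])
        got = [(p.interval.chrom, p.interval.start, p.interval.end) for p in u.peaks]
        assert sorted(got) == merge_oracle(ivs)


class TestExcludeRepeats:
    def test_empty_repeat_set_is_identity(self, rng):
        peaks = random_peaks(rng, 10)
        assert exclude_repeats(peaks, []) == peaks

    def test_peak_inside_repeat_removed(self):
        pk = SummitPeak(GenomicInterval("chr1", 100, 200), 150, "a")
        assert exclude_repeats([pk], [GenomicInterval("chr1", 50, 300)]) == []

    def test_random_case_matches_overlap_oracle(self, rng):
        peaks = random_peaks(rng, 200, max_pos=30000)
        repeats = random_intervals(rng, 50, max_pos=30000)
        kept = exclude_repeats(peaks, repeats)
        expect = [
            p for p in peaks
            if not any(p.interval.overlaps(r) for r in repeats)
        ]
        assert kept == expect


class TestClassifySpecific:
    def _cols(self, a1, a2, b1, b2):
        idx = [f"pk{i}" for i in range(len(a1))]
        return (pd.Series(a1, index=idx, dtype=float), pd.Series(a2, index=idx, dtype=float),
                pd.Series(b1, index=idx, dtype=float), pd.Series(b2, index=idx, dtype=float))

    def test_two_fold_in_both_replicates_is_specific(self):
        lab = classify_specific(*self._cols([40], [44], [10], [9]))
        assert lab.label.iloc[0] == "A_specific"
        assert lab.fc_rep1.iloc[0] == pytest.approx(41 / 11)

    def test_single_replicate_failure_is_shared(self):
        lab = classify_specific(*self._cols([40], [15], [10], [9]))
        assert lab.label.iloc[0] == "shared"  # second replicate 16/10 < 2

    def test_mismatched_universes_error(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError, match="universe"):
            classify_specific(a, a, a, b)

    def test_swapping_conditions_swaps_labels(self, rng):
        cols = [pd.Series(rng.integers(0, 200, 500).astype(float),
                          index=[f"pk{i}" for i in range(500)]) for _ in range(4)]
        fwd = classify_specific(cols[0], cols[1], cols[2], cols[3])
        rev = classify_specific(cols[2], cols[3], cols[0], cols[1])
        swap = {"A_specific": "B_specific", "B_specific": "A_specific", "shared": "shared"}
        assert (fwd.label.map(swap) == rev.label).all()

    def test_labels_match_per_peak_oracle_and_nest_with_fc(self, rng):
        n = 10000
        idx = [f"pk{i}" for i in range(n)]
        cols = [pd.Series(rng.integers(0, 300, n).astype(float), index=idx) for _ in range(4)]
        lab2 = classify_specific(*cols, fc=2.0)
        for i in rng.integers(0, n, size=200):  # spot-check against scalar recomputation
            a1, a2, b1, b2 = (float(c.iloc[i]) for c in cols)
            r1, r2 = (a1 + 1) / (b1 + 1), (a2 + 1) / (b2 + 1)
            if r1 >= 2 and r2 >= 2:
                expect = "A_specific"
            elif r1 <= 0.5 and r2 <= 0.5:
                expect = "B_specific"
            else:
                expect = "shared"
            assert lab2.label.iloc[i] == expect
        lab4 = classify_specific(*cols, fc=4.0)
        set2 = set(lab2.index[lab2.label == "A_specific"])
        set4 = set(lab4.index[lab4.label == "A_specific"])
        assert set4 <= set2

    def test_every_peak_gets_exactly_one_label(self, rng):
        n = 1000
        idx = [f"pk{i}" for i in range(n)]
        cols = [pd.Series(rng.integers(0, 100, n).astype(float), index=idx) for _ in range(4)]
        lab = classify_specific(*cols)
        assert lab.label.isin(["A_specific", "B_specific", "shared"]).all()
        assert len(lab) == n


class TestInducibleFilter:
    def test_above_threshold_retained(self):
        stim = pd.Series({"a": 30.0})
        rest = pd.Series({"a": 9.0})
        assert inducible_filter(["a"], stim, rest, fc=3.0) == ["a"]  # 31/10 = 3.1

    def test_exact_threshold_retained(self):
        stim = pd.Series({"a": 29.0})
        rest = pd.Series({"a": 9.0})
        assert inducible_filter(["a"], stim, rest, fc=3.0) == ["a"]  # 30/10 = 3.0

    def test_fc_grid_gives_nested_subsets(self, rng):
        n = 2000
        idx = [f"pk{i}" for i in range(n)]
        stim = pd.Series(rng.integers(0, 300, n).astype(float), index=idx)
        rest = pd.Series(rng.integers(0, 100, n).astype(float), index=idx)
        prev = set(idx)
        for fc in (1.5, 2.0, 3.0, 5.0):
            cur = set(inducible_filter(idx, stim, rest, fc=fc))
            assert cur <= prev
            prev = cur


class TestCountRateTest:
    def _df(self, arr, prefix):
        arr = np.asarray(arr)
        return pd.DataFrame(arr, index=[f"pk{i}" for i in range(arr.shape[0])],
                            columns=[f"{prefix}{j}" for j in range(arr.shape[1])])

    def test_identical_columns_are_null(self, rng):
        a = rng.integers(10, 500, size=(300, 2))
        res = count_rate_test(self._df(a, "a"), self._df(a, "b"))
        assert (res.pvalue >= 0.5).all()

    def test_single_replicate_errors(self, rng):
        a = self._df(rng.integers(0, 50, size=(10, 2)), "a")
        with pytest.raises(ValueError, match="replicates"):
            count_rate_test(a, a[["a0"]])

    def test_planted_eightfold_changes_are_detected(self):
        g = np.random.default_rng(7)
        n, n_planted = 2000, 200
        mu = np.full(n, 200.0)
        disp = 0.05
        r = 1 / disp
        draw = lambda m: g.negative_binomial(r, r / (r + m), size=(2, len(m))).T
        a = draw(mu)
        mu_b = mu.copy()
        mu_b[:n_planted] *= 8.0
        b = draw(mu_b)
        res = count_rate_test(self._df(a, "a"), self._df(b, "b"))
        planted_q = res.qvalue.iloc[:n_planted]
        assert (planted_q < 0.05).mean() >= 0.95

    def test_bh_matches_step_up_oracle(self, rng):
        a = rng.integers(0, 400, size=(500, 2))
        b = rng.integers(0, 400, size=(500, 2))
        res = count_rate_test(self._df(a, "a"), self._df(b, "b"))
        np.testing.assert_allclose(res.qvalue, bh_oracle(res.pvalue), rtol=1e-12)


class TestConcordance:
    def test_fold_change_calls_are_backed_by_the_rate_test(self):
        """Most fold-change-classified specific peaks also reach q < 0.05,
        mirroring the expected cross-method agreement."""
        from chromaprime.quantify import correction_factors, normalize, scaled_top_n
        bundle = simulate(SimulationParams(seed=7, n_peaks=5000, n_genes=50,
                                           n_group_genes=10, n_t0_group_genes=5,
                                           n_profile_peaks=10))
        counts = bundle.counts
        nf = correction_factors(counts, scaled_top_n(len(counts)))
        nm = normalize(counts, nf)
        lab = classify_specific(nm["T_0_rep1"], nm["T_0_rep2"], nm["N_0_rep1"], nm["N_0_rep2"])
        spec = lab.index[lab.label != "shared"]
        t_reps, n_reps = ["T_0_rep1", "T_0_rep2"], ["N_0_rep1", "N_0_rep2"]
        res = count_rate_test(
            counts[t_reps], counts[n_reps],
            size_factorsA=1.0 / np.array([nf.factors[s] for s in t_reps]),
            size_factorsB=1.0 / np.array([nf.factors[s] for s in n_reps]),
        )
        agree = (res.loc[spec, "qvalue"] < 0.05).mean()
        assert agree >= 0.80
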