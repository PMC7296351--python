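"""Density matrices, motif scanning, footprint scoring, cut profiles."""
import itertools
import re

import numpy as np
import pytest

from chromaprime.core import CutTrack, GenomicInterval, SummitPeak
from chromaprime.profiles import (
    IUPAC,
    MotifHit,
    average_profile,
    call_footprints,
    cut_profile_around_motifs,
    footprint_score_closed_form,
    motif_presence_matrix,
    reverse_complement,
    scan_motif,
    tag_density_matrix,
)
from chromaprime.simulate import simulate_footprint_windows, simulate_poisson_null_windows

from conftest import random_peaks, random_track

SIZES = {"chr1": 50000}


def peak(pid, summit, width=400):
    return SummitPeak(GenomicInterval("chr1", summit - width // 2, summit + width // 2), summit, pid)


class TestDensityMatrix:
    def test_zero_track_gives_zero_matrix(self):
        dm = tag_density_matrix([peak("p", 5000)], CutTrack(SIZES), window=2000, bin_size=10)
        assert dm.shape == (1, 200)
        assert (dm.to_numpy() == 0).all()

    def test_single_cut_at_summit_hits_central_bin(self):
        plus = {"chr1": np.zeros(SIZES["chr1"], dtype=np.int64)}
        plus["chr1"][5000] = 1
        track = CutTrack(SIZES, plus=plus)
        dm = tag_density_matrix([peak("p", 5000)], track, window=2000, bin_size=10)
        assert dm.loc["p", "0"] == 1
        assert dm.to_numpy().sum() == 1

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            tag_density_matrix([], CutTrack(SIZES), window=2000, bin_size=7)

    def test_rows_follow_given_order_and_sums_conserve(self, rng):
        track = random_track(rng, SIZES, rate=0.1)
        peaks = random_peaks(rng, 30, chroms=("chr1",), max_pos=40000, prefix="q")
        dm = tag_density_matrix(peaks, track, window=400, bin_size=10)
        assert list(dm.index) == [p.peak_id for p in peaks]
        for p in peaks:  # per-base oracle
            expect = track.window_sum("chr1", p.summit - 200, p.summit + 200)
            assert dm.loc[p.peak_id].sum() == expect


class TestAverageProfile:
    def test_identical_rows_average_to_any_row(self):
        plus = {"chr1": np.zeros(SIZES["chr1"], dtype=np.int64)}
        for s in (5000, 9000):
            plus["chr1"][s - 3:s + 3] = 2
        track = CutTrack(SIZES, plus=plus)
        peaks = [peak("a", 5000), peak("b", 9000)]
        prof = average_profile(peaks, track, window=400, bin_size=10)
        dm = tag_density_matrix(peaks, track, window=400, bin_size=10)
        np.testing.assert_allclose(prof.to_numpy(), dm.iloc[0].to_numpy())

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError):
            average_profile([], CutTrack(SIZES))


def _iupac_regex(consensus):
    return re.compile("".join(f"[{IUPAC[c]}]" for c in consensus))


class TestMotifScan:
    def _seq_fixture(self, seqs, width=200):
        peaks = [peak(f"p{i}", 1000 + 1000 * i, width=400) for i in range(len(seqs))]
        return {p.peak_id: s for p, s in zip(peaks, seqs)}, peaks

    def test_ap1_site_found(self):
        seqs, peaks = self._seq_fixture(["AAATGACTCAAAA"])
        hits = scan_motif("TGASTCA", seqs, peaks, halfwidth=100)
        # TGACTCA is its own reverse complement -> one hit per strand
        assert {(h.strand, h.matched) for h in hits} == {("+", "TGACTCA"), ("-", "TGACTCA")}
        assert hits[0].start == peaks[0].summit - 100 + 3

    def test_no_match_returns_empty(self):
        seqs, peaks = self._seq_fixture(["AAAAAAAAAA"])
        assert scan_motif("TGASTCA", seqs, peaks) == []

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("TGAXTCA", {}, [])

    def test_minus_strand_match_detected(self):
        # reverse complement of TGAGTCA is TGACTCA; embed TGAGTCA's RC
        seqs, peaks = self._seq_fixture(["CCTGACTCACC"])
        hits = scan_motif("TGASTCA", seqs, peaks)
        assert any(h.strand == "-" for h in hits)

    def test_all_iupac_letters_match_exhaustive_oracle(self, rng):
        bases = "ACGT"
        seqs = ["".join(bases[i] for i in rng.integers(0, 4, size=120)) for _ in range(5)]
        seq_map, peaks = self._seq_fixture(seqs)
        for consensus in ("RYK", "SWN", "BDHV", "MAC", "TGASTCA", "GGGRNNYYCC"):
            hits = scan_motif(consensus, seq_map, peaks, halfwidth=60)
            fwd, rc = _iupac_regex(consensus), _iupac_regex(reverse_complement(consensus))
            expect = 0
            for s in seqs:
                for off in range(len(s) - len(consensus) + 1):
                    win = s[off:off + len(consensus)]
                    expect += bool(fwd.fullmatch(win)) + bool(rc.fullmatch(win))
            assert len(hits) == expect


class TestPresenceMatrix:
    def test_zero_and_single_hit(self):
        peaks = [peak("a", 5000), peak("b", 9000)]
        hit = MotifHit("AP-1", "chr1", 5000, 5007, "+", "TGACTCA", "a")
        m = motif_presence_matrix(peaks, {"AP-1": [hit], "NFAT": []})
        assert m.loc["a", "AP-1"] == 1
        assert m.loc["b", "AP-1"] == 0
        assert (m["NFAT"] == 0).all()

    def test_matches_membership_oracle(self, rng):
        peaks = random_peaks(rng, 20, chroms=("chr1",), prefix="m")
        hits = [
            MotifHit("X", "chr1", 0, 5, "+", "AAAAA", p.peak_id)
            for p in peaks if rng.random() < 0.5
        ]
        m = motif_presence_matrix(peaks, {"X": hits})
        have = {h.peak_id for h in hits}
        for p in peaks:
            assert m.loc[p.peak_id, "X"] == (1 if p.peak_id in have else 0)


class TestFootprintScore:
    def test_zero_cut_candidate_matches_binomial_closed_form(self):
        p = footprint_score_closed_form(0, 200, 15, 35)
        assert p == pytest.approx((1 - 15 / 85) ** 200, abs=1e-12)

    def test_score_monotone_decreasing_in_candidate_cuts(self):
        ps = [footprint_score_closed_form(k, 200, 15, 35) for k in range(0, 40, 5)]
        assert ps == sorted(ps)  # larger candidate count -> larger tail p

    def test_uniform_cuts_not_called(self, rng):
        peaks, track = simulate_poisson_null_windows(50, seed=3)
        calls = call_footprints(peaks, track)
        assert sum(c.called for c in calls) == 0

    def test_low_coverage_flagged_not_evaluable(self):
        size = 2000
        plus = {"chrP": np.zeros(size, dtype=np.int64)}
        plus["chrP"][500] = 5  # far below min_cuts
        track = CutTrack({"chrP": size}, plus=plus)
        pk = SummitPeak(GenomicInterval("chrP", 300, 700), 500, "low")
        calls = call_footprints([pk], track)
        assert not calls[0].evaluable and not calls[0].called

    def test_planted_footprints_recovered(self):
        peaks, track, planted = simulate_footprint_windows(150, seed=9)
        calls = call_footprints(peaks, track)
        called = {c.peak_id for c in calls if c.called}
        pset = {p for p, b in planted.items() if b}
        assert len(called & pset) / len(pset) >= 0.8
        assert len(called - pset) <= 0.1 * max(1, len(called))


class TestCutProfiles:
    def test_single_cut_lands_at_relative_position(self):
        plus = {"chr1": np.zeros(SIZES["chr1"], dtype=np.int64)}
        plus["chr1"][5010] = 3
        track = CutTrack(SIZES, plus=plus)
        hit = MotifHit("X", "chr1", 4995, 5005, "+", "A" * 10, "p")
        fwd, rev = cut_profile_around_motifs([hit], track, window=100)
        # motif center 5000, window starts at 4950 -> position 60
        assert fwd[60] == 3.0 and rev.sum() == 0.0

    def test_minus_strand_hit_is_flipped(self):
        plus = {"chr1": np.zeros(SIZES["chr1"], dtype=np.int64)}
        minus = {"chr1": np.zeros(SIZES["chr1"], dtype=np.int64)}
        minus["chr1"][5010] = 2  # 10 bp right of center on the - strand
        track = CutTrack(SIZES, plus=plus, minus=minus)
        hit = MotifHit("X", "chr1", 4995, 5005, "-", "A" * 10, "p")
        fwd, rev = cut_profile_around_motifs([hit], track, window=100)
        # flipped: appears on the forward profile 10 bp left of center (pos 39)
        assert fwd[39] == 2.0 and rev.sum() == 0.0

    def test_empty_hits_error(self):
        with pytest.raises(ValueError):
            cut_profile_around_motifs([], CutTrack(SIZES))

    def test_matches_per_hit_accumulation_oracle(self, rng):
        track = random_track(rng, SIZES, rate=0.1)
        hits = [
            MotifHit("X", "chr1", s, s + 10, "+" if rng.random() < 0.5 else "-", "A" * 10, f"p{i}")
            for i, s in enumerate(rng.integers(1000, 40000, size=25))
        ]
        fwd, rev = cut_profile_around_motifs(hits, track, window=60)
        exp_f = np.zeros(60)
        exp_r = np.zeros(60)
        for h in hits:
            center = (h.start + h.end) // 2
            pw = track.plus["chr1"][center - 30:center + 30].astype(float)
            mw = track.minus["chr1"][center - 30:center + 30].astype(float)
            if h.strand == "-":
                pw, mw = mw[::-1], pw[::-1]
            exp_f += pw
            exp_r += mw
        np.testing.assert_allclose(fwd, exp_f / len(hits))
        np.testing.assert_allclose(rev, exp_r / len(hits))
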