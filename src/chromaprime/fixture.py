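"""A deterministic 30-peak / 20-gene micro-dataset with a hand-computed key.

Every pipeline threshold is exercised at its boundary: fold-change
ratios landing exactly on 2.0, 3.0, and 10.0 after the pseudocount,
an expression value exactly at the min-count of 50 and at the universe
mean of 3, and TSS-to-summit distances of exactly 50 kb and 100 kb.
The answer key was computed by hand from the printed values and is the
oracle for the integration tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneRecord, GenomicInterval, SummitPeak


def _peak(i: int, summit: int) -> SummitPeak:
    return SummitPeak(GenomicInterval("chrF", summit - 200, summit + 200), summit, f"pk{i:02d}")


@dataclass
class WorkedFixture:
    peaks: list[SummitPeak]
    counts: pd.DataFrame  # normalized counts: T0_rep1/2, N0_rep1/2, TAg_rep1
    genes: list[GeneRecord]
    repeats: list[GenomicInterval]
    chip_peaks: list[GenomicInterval]
    answer_key: dict


def worked_fixture() -> WorkedFixture:
    """Build the micro-dataset and its hand-computed answer key.

    Conventions: pseudocount 1.0 everywhere; specific DHSs at >= 2-fold
    in both replicates (T_0 vs N_0); iDHSs additionally >= 3-fold in
    T_Ag over the T_0 replicate mean; gene groups at 2-fold with
    min-count 50 over a universe of mean >= 3; high variation at 10-fold;
    proximity at <= 50 kb, closest-gene cap at 100 kb.
    """
    summits = {i: 200_000 + i * 120_000 for i in range(30)}
    peaks = [_peak(i, summits[i]) for i in range(30)]

    # (T0_r1, T0_r2, N0_r1, N0_r2, TAg); ratios quoted after +1 pseudocount
    rows: dict[str, tuple[float, float, float, float, float]] = {}
    rows["pk00"] = (39, 39, 19, 19, 119)   # 40/20 = 2.0 both -> A; TAg 120/40 = 3.0 -> inducible
    rows["pk01"] = (40, 44, 10, 9, 128)    # 3.73 / 4.5 -> A; TAg 129/43 = 3.0 -> inducible
    rows["pk02"] = (40, 15, 10, 9, 28)     # 3.73 / 1.6 -> shared
    rows["pk03"] = (19, 19, 39, 39, 19)    # 0.5 both -> B (boundary)
    rows["pk04"] = (9, 9, 99, 99, 9)       # 0.1 -> B
    rows["pk05"] = (50, 50, 50, 50, 50)    # shared
    rows["pk06"] = (79, 79, 19, 19, 79)    # 4.0 -> A; TAg 80/80 = 1.0 -> not inducible
    rows["pk07"] = (79, 79, 19, 19, 319)   # 4.0 -> A; TAg 320/80 = 4.0 -> inducible
    rows["pk08"] = (79, 79, 19, 19, 159)   # 4.0 -> A; TAg 160/80 = 2.0 -> not inducible
    rows["pk09"] = (79, 79, 19, 19, 82)    # 4.0 -> A; TAg 83/80 -> not inducible
    for i in range(10, 30):
        rows[f"pk{i:02d}"] = (50, 50, 50, 50, 50)
    counts = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["T0_rep1", "T0_rep2", "N0_rep1", "N0_rep2", "TAg_rep1"],
    ).astype(float)

    # genes: far block sits megabases away from every peak
    far = {i: 5_000_000 + i * 150_000 for i in range(20)}
    tss = dict(far)
    tss[5] = summits[0] + 50_000    # g05: exactly 50 kb from tDHS pk00
    tss[7] = summits[7] + 60_000    # g07: 60 kb from pk07/pk08 (tie), beyond 50 kb
    tss[6] = summits[9] + 100_000   # g06: exactly 100 kb from pk09, 20 kb from pk10

    E = {}  # gene -> (T_0, N_0, T_Ag, N_Ag)
    E[0] = (99, 49, 99, 99)       # T0: 100/50 = 2.0 -> T0-specific (boundary)
    E[1] = (199, 49, 199, 199)    # 4.0 -> T0-specific
    E[2] = (45, 10, 45, 45)       # 4.18 but max 45 < 50 -> excluded
    E[3] = (100, 40, 100, 100)    # 101/41 = 2.46 -> T0-specific
    E[4] = (49, 99, 49, 49)       # mirror -> N0-specific
    E[5] = (59, 59, 119, 59)      # TAg 120/60 = 2.0 spec, 120/60 = 2.0 induced -> TAg group
    E[6] = (119, 119, 119, 59)    # TAg specific 2.0 but TAg/T0 = 1.0 -> excluded
    E[7] = (39, 39, 199, 39)      # 200/40 = 5.0 -> TAg group
    E[8] = (59, 59, 59, 119)      # mirror -> NAg group (120/60 induced in naive arm)
    E[9] = (99, 9, 99, 99)        # T0:N0 = 100/10 = 10.0 -> high variation (boundary)
    E[10] = (98, 9, 98, 98)       # 99/10 = 9.9 -> below the 10-fold bar
    for i in range(11, 18):
        E[i] = (30, 30, 30, 30)
    E[18] = (3, 2, 2, 2)          # universe boundary: one mean exactly 3
    E[19] = (2.9, 2.9, 2.9, 2.9)  # below the universe threshold
    genes = [
        GeneRecord(
            f"g{i:02d}", "chrF", tss[i], "+",
            {"T_0": float(t0), "N_0": float(n0), "T_Ag": float(tag), "N_Ag": float(nag)},
        )
        for i, (t0, n0, tag, nag) in sorted(E.items())
    ]

    repeats = [GenomicInterval("chrF", summits[29] - 300, summits[29] + 300)]  # covers pk29
    chip_peaks = [
        GenomicInterval("chrF", summits[0] - 100, summits[0] + 100),  # hits iDHS pk00
        GenomicInterval("chrF", summits[1] - 100, summits[1] + 100),  # hits iDHS pk01
        GenomicInterval("chrF", 8_000_000, 8_000_200),
        GenomicInterval("chrF", 8_100_000, 8_100_200),
    ]

    answer_key = {
        "tdhs": ["pk00", "pk01", "pk06", "pk07", "pk08", "pk09"],
        "ndhs": ["pk03", "pk04"],
        "idhs": ["pk00", "pk01", "pk07"],
        "n_after_repeat_exclusion": 29,
        "universe": [f"g{i:02d}" for i in range(19)],  # g19 excluded
        # g09/g10 ride along: their 10- and 9.9-fold T0:N0 ratios clear the
        # 2-fold bar too, so the T0 group and the high-variation set overlap
        "t0_specific": ["g00", "g01", "g03", "g09", "g10"],
        "n0_specific": ["g04"],
        "tag_specific": ["g05", "g07"],
        "nag_specific": ["g08"],
        "high_variation": ["g09"],
        # of the TAg group, g05 sits exactly 50 kb from tDHS pk00; g07 is 60 kb out
        "fraction_tag_within_50kb": 0.5,
        "closest_gene": {"pk00": "g05", "pk09": "g06"},
        "venn_idhs_vs_chip": {"both_a": 2, "a_only": 1, "b_only": 2},
    }
    return WorkedFixture(peaks, counts, genes, repeats, chip_peaks, answer_key)
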