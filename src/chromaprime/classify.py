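"""Master peak unions and differential DHS classification.

A high-confidence condition-specific DHS must be at least ``fc``-fold
(default 2) higher in *both* replicate pairs, with a pseudocount (default
1.0) added to the normalized counts before taking ratios. Inducible DHSs
(iDHSs) are specific DHSs that are additionally at least ``fc``-fold
(default 3) higher after stimulation than at rest in the matched
condition. A lightweight overdispersed count-rate test with
Benjamini-Hochberg correction provides an FDR-controlled cross-check of
the fold-change calls; it is a surrogate for a full negative-binomial
GLM, not a clone of one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, SummitPeak
from .intervals import merge_intervals, overlaps_any


# ---------------------------------------------------------------------------
# Unions
# ---------------------------------------------------------------------------

def significant_peaks(column: pd.Series, cutoff: float) -> list[str]:
    """Peak ids whose normalized count is at least ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return list(column.index[column >= cutoff])


@dataclass
class UnionPeakSet:
    """Merged peak intervals with provenance and a representative summit."""

    peaks: list[SummitPeak]
    provenance: list[list[str]]  # contributing input peak_ids per merged peak

    def __post_init__(self) -> None:
        for prov in self.provenance:
            if not prov:
                raise ValueError("merged peak with empty provenance")


def merge_union(
    sets: list[list[SummitPeak]],
    counts: pd.Series | None = None,
) -> UnionPeakSet:
    """Merge peak sets into a union of non-overlapping peaks.

    Overlapping or bookended (gap 0) intervals merge. The representative
    summit of a merged peak is the summit of the contributing peak with
    the highest normalized count in ``counts`` (ties and missing counts
    resolve to the smaller summit coordinate).
    """
    flat: list[SummitPeak] = [p for s in sets for p in s]
    if not flat:
        return UnionPeakSet([], [])
    merged, members = merge_intervals([p.interval for p in flat])
    out_peaks: list[SummitPeak] = []
    prov: list[list[str]] = []
    for k, (iv, mem) in enumerate(zip(merged, members)):
        contributors = [flat[i] for i in mem]

        def key(p: SummitPeak) -> tuple:
            c = float(counts.get(p.peak_id, 0.0)) if counts is not None else 0.0
            return (-c, p.summit)

        rep = min(contributors, key=key)
        out_peaks.append(SummitPeak(iv, rep.summit, f"union_{k:06d}"))
        prov.append([p.peak_id for p in contributors])
    return UnionPeakSet(out_peaks, prov)


def exclude_repeats(
    peaks: list[SummitPeak],
    repeat_intervals: list[GenomicInterval],
    min_overlap: int = 1,
) -> list[SummitPeak]:
    """Drop peaks overlapping any repeat interval by >= min_overlap bp."""
    if not repeat_intervals or not peaks:
        return list(peaks)
    mask = overlaps_any([p.interval for p in peaks], repeat_intervals, min_overlap)
    return [p for p, hit in zip(peaks, mask) if not hit]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class DHSClassLabel:
    peak_id: str
    label: str  # A_specific | B_specific | shared | insignificant
    fold_changes: dict[str, float] = field(default_factory=dict)
    inducible: bool = False
    pseudocount: float = 1.0


_LABELS = ("A_specific", "B_specific", "shared", "insignificant")


def _aligned(*columns: pd.Series) -> None:
    base = columns[0].index
    for col in columns[1:]:
        if not base.equals(col.index):
            raise ValueError("mismatched peak universes between count columns")


def classify_specific(
    countsA_rep1: pd.Series,
    countsA_rep2: pd.Series,
    countsB_rep1: pd.Series,
    countsB_rep2: pd.Series,
    fc: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Replicate-consistent specific-DHS labels for a pair of conditions.

    A peak is A_specific iff (A_i + p) / (B_i + p) >= fc in both
    replicate pairs i = 1, 2; B_specific symmetrically; otherwise shared.
    Returns a DataFrame indexed by peak_id with columns label, fc_rep1,
    fc_rep2 (A over B, pseudocounted).
    """
    if fc <= 1:
        raise ValueError("fc must exceed 1")
    _aligned(countsA_rep1, countsA_rep2, countsB_rep1, countsB_rep2)
    p = pseudocount
    r1 = (countsA_rep1 + p) / (countsB_rep1 + p)
    r2 = (countsA_rep2 + p) / (countsB_rep2 + p)
    a_spec = (r1 >= fc) & (r2 >= fc)
    b_spec = (r1 <= 1 / fc) & (r2 <= 1 / fc)
    labels = np.where(a_spec, "A_specific", np.where(b_spec, "B_specific", "shared"))
    return pd.DataFrame(
        {"label": labels, "fc_rep1": r1, "fc_rep2": r2}, index=countsA_rep1.index
    )


def inducible_filter(
    specific_peak_ids: list[str],
    counts_stim: pd.Series,
    counts_rest: pd.Series,
    fc: float = 3.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Retain specific peaks at least fc-fold higher stimulated than resting."""
    _aligned(counts_stim, counts_rest)
    p = pseudocount
    ratio = (counts_stim + p) / (counts_rest + p)
    keep = ratio >= fc
    return [pid for pid in specific_peak_ids if bool(keep.get(pid, False))]


# ---------------------------------------------------------------------------
# Count-rate cross-check
# ---------------------------------------------------------------------------

def estimate_dispersion(columns: np.ndarray, size_factors: np.ndarray) -> float:
    """Method-of-moments overdispersion from replicate disagreement.

    For factor-adjusted replicate counts x with common mean m, an NB-type
    noise model gives Var(x) = m + a m^2; a is estimated as the median
    over peaks of (s^2 - m) / m^2, clipped at 0.
    """
    adj = columns / size_factors[None, :]
    m = adj.mean(axis=1)
    s2 = adj.var(axis=1, ddof=1)
    ok = m > 1.0
    if not np.any(ok):
        return 0.0
    a = (s2[ok] - m[ok]) / m[ok] ** 2
    return float(max(0.0, np.median(a)))


def count_rate_test(
    countsA: pd.DataFrame,
    countsB: pd.DataFrame,
    size_factorsA: np.ndarray | None = None,
    size_factorsB: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-sided test of equal cut rates between two replicate groups.

    Normal approximation on the log ratio of factor-adjusted mean counts;
    the variance combines Poisson counting noise of the pooled raw counts
    with an overdispersion term estimated from replicate disagreement.
    Benjamini-Hochberg adjusted q-values are returned alongside.
    """
    if countsA.shape[1] < 2 or countsB.shape[1] < 2:
        raise ValueError("need at least 2 replicates per side")
    if not countsA.index.equals(countsB.index):
        raise ValueError("mismatched peak universes")
    sfA = np.ones(countsA.shape[1]) if size_factorsA is None else np.asarray(size_factorsA, float)
    sfB = np.ones(countsB.shape[1]) if size_factorsB is None else np.asarray(size_factorsB, float)
    A = countsA.to_numpy(dtype=float)
    B = countsB.to_numpy(dtype=float)
    dispersion = max(
        estimate_dispersion(A, sfA), estimate_dispersion(B, sfB)
    )
    p = pseudocount
    mA = (A / sfA[None, :]).mean(axis=1) + p
    mB = (B / sfB[None, :]).mean(axis=1) + p
    log_ratio = np.log(mA) - np.log(mB)
    nA, nB = A.shape[1], B.shape[1]
    # Var(log mean) ~ (1/mean + dispersion) / n_reps per side
    var = (1.0 / mA + dispersion) / nA + (1.0 / mB + dispersion) / nB
    z = log_ratio / np.sqrt(var)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"log_ratio": log_ratio, "z": z, "pvalue": pvals, "qvalue": qvals,
         "dispersion": dispersion},
        index=countsA.index,
    )
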