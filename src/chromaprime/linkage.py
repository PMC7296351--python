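"""DHS-gene proximity, interval binning, set overlaps, and permutation nulls.

Distances are unsigned summit-to-TSS base pairs on the same chromosome.
Peaks are assigned to the closest gene within a cap (100 kb by default);
gene groups are characterized by the fraction of members whose TSS lies
within a distance (50 kb) of the nearest DHS of a set, with a label
permutation over the expressed universe providing the enrichment null.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .core import GeneRecord, GenomicInterval, SummitPeak
from .intervals import merge_intervals


def closest_tss_assignment(
    peaks: list[SummitPeak],
    genes: list[GeneRecord],
    max_dist: int = 100000,
) -> dict[str, str | None]:
    """Map each peak to the gene with minimal |summit - TSS| <= max_dist.

    Ties break to the smaller TSS coordinate, then lexicographic gene_id;
    peaks with no gene in range map to None.
    """
    genes_by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    out: dict[str, str | None] = {}
    for p in peaks:
        best: tuple[float, int, str] | None = None
        for g in genes_by_chrom.get(p.chrom, ()):
            d = abs(p.summit - g.tss)
            if d > max_dist:
                continue
            key = (d, g.tss, g.gene_id)
            if best is None or key < best:
                best = key
        out[p.peak_id] = best[2] if best is not None else None
    return out


def nearest_dhs_distance(
    genes: list[GeneRecord], dhs_set: list[SummitPeak]
) -> dict[str, float]:
    """Per-gene distance to the nearest DHS summit (inf if none on chrom)."""
    summits_by_chrom: dict[str, list[int]] = defaultdict(list)
    for p in dhs_set:
        summits_by_chrom[p.chrom].append(p.summit)
    sorted_summits = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in summits_by_chrom.items()}
    out: dict[str, float] = {}
    for g in genes:
        sp = sorted_summits.get(g.chrom)
        if sp is None or sp.size == 0:
            out[g.gene_id] = float("inf")
            continue
        i = int(np.searchsorted(sp, g.tss))
        best = float("inf")
        if i < sp.size:
            best = abs(int(sp[i]) - g.tss)
        if i > 0:
            best = min(best, abs(g.tss - int(sp[i - 1])))
        out[g.gene_id] = float(best)
    return out


def fraction_within(
    genes: list[GeneRecord], dhs_set: list[SummitPeak], dist: int
) -> float:
    """Fraction of genes whose nearest DHS lies within dist bp of the TSS."""
    if not genes:
        raise ValueError("empty gene group")
    d = nearest_dhs_distance(genes, dhs_set)
    return sum(1 for v in d.values() if v <= dist) / len(genes)


def distance_bins(
    genes: list[GeneRecord], dhs_set: list[SummitPeak], edges: list[int]
) -> dict[str, float]:
    """Fractions of genes per half-open distance bin, plus a beyond/inf bin.

    Bins are [0, e1), [e1, e2), ..., [e_last, inf]; fractions sum to 1.
    """
    if not genes:
        raise ValueError("empty gene group")
    e = list(edges)
    if any(b <= a for a, b in zip(e, e[1:])) or not e:
        raise ValueError("edges must be strictly increasing and non-empty")
    d = np.array(list(nearest_dhs_distance(genes, dhs_set).values()))
    out: dict[str, float] = {}
    lo = 0
    for hi in e:
        out[f"[{lo},{hi})"] = float(np.mean((d >= lo) & (d < hi)))
        lo = hi
    out[f"[{lo},inf]"] = float(np.mean(d >= lo))
    return out


@dataclass
class OverlapVenn:
    set_a: str
    set_b: str
    a_only: int
    b_only: int
    both_a: int  # A peaks touching >=1 B peak
    both_b: int  # B peaks touching >=1 A peak
    min_overlap: int

    @property
    def n_a(self) -> int:
        return self.a_only + self.both_a

    @property
    def n_b(self) -> int:
        return self.b_only + self.both_b


def overlap_venn(
    setA: list[GenomicInterval],
    setB: list[GenomicInterval],
    min_overlap: int = 1,
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapVenn:
    """A-side Venn counts after merging each set internally.

    Each merged A peak counts once in ``both_a`` if it overlaps any merged
    B peak by >= min_overlap bp (and symmetrically for ``both_b``), so
    a_only + both_a = |merged A|.
    """
    mA, _ = merge_intervals(setA)
    mB, _ = merge_intervals(setB)

    def count_hits(query: list[GenomicInterval], subject: list[GenomicInterval]) -> int:
        subj: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom = defaultdict(list)
        for iv in subject:
            by_chrom[iv.chrom].append(iv)
        for c, ivs in by_chrom.items():
            subj[c] = (
                np.array([x.start for x in ivs], dtype=np.int64),
                np.array([x.end for x in ivs], dtype=np.int64),
            )
        hits = 0
        for iv in query:
            if iv.chrom not in subj:
                continue
            starts, ends = subj[iv.chrom]
            ov = np.minimum(iv.end, ends) - np.maximum(iv.start, starts)
            if np.any(ov >= min_overlap):
                hits += 1
        return hits

    both_a = count_hits(mA, mB)
    both_b = count_hits(mB, mA)
    return OverlapVenn(
        set_a=name_a, set_b=name_b,
        a_only=len(mA) - both_a, b_only=len(mB) - both_b,
        both_a=both_a, both_b=both_b, min_overlap=min_overlap,
    )


def permutation_enrichment(
    gene_group: list[GeneRecord],
    dhs_set: list[SummitPeak],
    universe: list[GeneRecord],
    dist: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation p-value for proximity enrichment of a gene group.

    The observed within-``dist`` fraction of the group is compared with
    fractions of ``n_perm`` random same-size groups drawn from the
    expressed universe: p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    group_ids = {g.gene_id for g in gene_group}
    uni_ids = [g.gene_id for g in universe]
    if not group_ids <= set(uni_ids):
        raise ValueError("gene_group must be a subset of the universe")
    if len(group_ids) == len(uni_ids):
        raise ValueError("gene_group equals the universe; null is empty")
    d = nearest_dhs_distance(universe, dhs_set)
    near = np.array([d[gid] <= dist for gid in uni_ids], dtype=float)
    obs = float(np.mean([d[gid] <= dist for gid in group_ids]))
    rng = np.random.default_rng(seed)
    k = len(group_ids)
    perm_fracs = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(uni_ids), size=k, replace=False)
        perm_fracs[i] = near[idx].mean()
    p = (1.0 + float(np.sum(perm_fracs >= obs))) / (n_perm + 1.0)
    return {
        "observed_fraction": obs,
        "null_mean_fraction": float(perm_fracs.mean()),
        "p_value": p,
        "n_perm": n_perm,
        "n_group": k,
        "dist": dist,
    }


def ranked_fc_annotation(
    ranked_peaks: list[SummitPeak],
    genes: list[GeneRecord],
    gene_fc: dict[str, float],
    max_dist: int = 100000,
) -> list[float | None]:
    """Closest-gene expression fold change aligned to a DHS ranking.

    For each peak (in the given fold-change order) the closest gene's
    fold change is carried over; peaks with no gene within max_dist get
    None.
    """
    assign = closest_tss_assignment(ranked_peaks, genes, max_dist)
    out: list[float | None] = []
    for p in ranked_peaks:
        gid = assign[p.peak_id]
        out.append(None if gid is None else float(gene_fc.get(gid, np.nan)))
    return out
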