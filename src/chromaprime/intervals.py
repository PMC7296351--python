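"""Low-level interval sweeps shared by the classification and linkage stages.

All routines operate per chromosome on sorted coordinate arrays and use
half-open [start, end) intervals. Merging treats bookended intervals
(gap 0) as overlapping, matching sort|merge behaviour of the standard
BED toolchain.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np

from .core import GenomicInterval


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    d: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        d[iv.chrom].append(iv)
    return d


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[list[int]]]:
    """Merge overlapping or bookended intervals.

    Returns the merged intervals (sorted) and, for each, the indices of
    the input intervals it absorbed (provenance).
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    merged: list[GenomicInterval] = []
    members: list[list[int]] = []
    cur = None  # (chrom, start, end, member indices)
    for i in order:
        iv = intervals[i]
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), cur[3] + [i])
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
                members.append(cur[3])
            cur = (iv.chrom, iv.start, iv.end, [i])
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
        members.append(cur[3])
    return merged, members


def overlaps_any(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean mask: does each query interval overlap >=1 subject by >= min_overlap bp."""
    subj_merged = _by_chrom(subject)
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in subj_merged.items():
        ivs = sorted(ivs, key=lambda x: (x.start, x.end))
        starts_ends[chrom] = (
            np.array([x.start for x in ivs], dtype=np.int64),
            np.array([x.end for x in ivs], dtype=np.int64),
        )
    mask = np.zeros(len(query), dtype=bool)
    for qi, iv in enumerate(query):
        if iv.chrom not in starts_ends:
            continue
        starts, ends = starts_ends[iv.chrom]
        # candidates: subjects with start < iv.end and end > iv.start
        lo = np.searchsorted(starts, iv.end - min_overlap, side="right")
        for j in range(lo):
            ov = min(iv.end, ends[j]) - max(iv.start, starts[j])
            if ov >= min_overlap:
                mask[qi] = True
                break
    return mask


def nearest_point_distance(
    query_points: np.ndarray, subject_points: np.ndarray
) -> np.ndarray:
    """For each query point, |query - nearest subject point| (inf if none).

    Both arrays are positions on the same chromosome; subject need not be
    sorted.
    """
    out = np.full(len(query_points), np.inf)
    if len(subject_points) == 0:
        return out
    sp = np.sort(np.asarray(subject_points, dtype=np.int64))
    idx = np.searchsorted(sp, query_points)
    for k, (q, i) in enumerate(zip(query_points, idx)):
        best = np.inf
        if i < len(sp):
            best = abs(int(sp[i]) - int(q))
        if i > 0:
            best = min(best, abs(int(q) - int(sp[i - 1])))
        out[k] = best
    return out
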