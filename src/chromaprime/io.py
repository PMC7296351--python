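"""Readers and writers for the plain-text formats the pipeline touches.

BED intervals (3-6 columns, with an optional 7th summit column), paired
bedGraph cut tracks (one file per strand, 0-based half-open spans with
integer values), TSV count matrices (rows = peak_ids, columns =
sample_ids), and TSV gene tables.

A format error always names the offending line.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CutTrack, GeneRecord, GenomicInterval, SummitPeak, check_unique_peak_ids


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
    with_summits: bool = False,
) -> list[GenomicInterval] | list[SummitPeak]:
    """Read a BED file into sorted intervals (or summit peaks).

    Peak dialect (``with_summits=True``): columns are
    chrom, start, end, name, score, strand, summit — summit is an absolute
    0-based position inside [start, end).
    """
    intervals: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from e
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise FormatError(f"{path}:{lineno}: interval beyond chromosome end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            iv = GenomicInterval(chrom, start, end, strand)
            if with_summits:
                if len(fields) < 7:
                    raise FormatError(f"{path}:{lineno}: summit column (7) missing")
                name = fields[3]
                try:
                    summit = int(fields[6])
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: non-integer summit") from e
                try:
                    intervals.append(SummitPeak(iv, summit, name))
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: {e}") from e
            else:
                intervals.append(iv)
    if with_summits:
        check_unique_peak_ids(intervals)
        intervals.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    else:
        intervals.sort()
    return intervals


def write_bed(path: str | Path, items: Sequence[GenomicInterval] | Sequence[SummitPeak]) -> None:
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, SummitPeak):
                iv = it.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{it.peak_id}\t0\t{iv.strand}\t{it.summit}\n"
                )
            else:
                fh.write(f"{it.chrom}\t{it.start}\t{it.end}\t.\t0\t{it.strand}\n")


# ---------------------------------------------------------------------------
# Cut tracks (paired bedGraph)
# ---------------------------------------------------------------------------

def _read_bedgraph_into(arrs: dict[str, np.ndarray], path: str | Path,
                        chrom_sizes: Mapping[str, int]) -> None:
    covered: dict[str, np.ndarray] = {c: np.zeros(s, dtype=bool) for c, s in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: need 4 bedGraph columns")
            chrom = fields[0]
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer field") from e
            if start >= end or start < 0 or end > chrom_sizes[chrom]:
                raise FormatError(f"{path}:{lineno}: span out of bounds")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative cut count")
            span = slice(start, end)
            prev = arrs[chrom][span]
            was = covered[chrom][span]
            if np.any(was & (prev != value)):
                raise FormatError(
                    f"{path}:{lineno}: overlapping spans with conflicting values"
                )
            arrs[chrom][span] = value
            covered[chrom][span] = True


def read_cut_track(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "",
) -> CutTrack:
    plus = {c: np.zeros(s, dtype=np.int64) for c, s in chrom_sizes.items()}
    minus = {c: np.zeros(s, dtype=np.int64) for c, s in chrom_sizes.items()}
    _read_bedgraph_into(plus, plus_path, chrom_sizes)
    _read_bedgraph_into(minus, minus_path, chrom_sizes)
    return CutTrack(chrom_sizes, sample_id=sample_id, plus=plus, minus=minus)


def _write_bedgraph(path: str | Path, arrs: Mapping[str, np.ndarray]) -> None:
    """Run-length encode a dense per-base array; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(arrs):
            a = arrs[chrom]
            if a.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [a.size]))
            for s, e in zip(starts, ends):
                v = int(a[s])
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_cut_track(plus_path: str | Path, minus_path: str | Path, track: CutTrack) -> None:
    _write_bedgraph(plus_path, track.plus)
    _write_bedgraph(minus_path, track.minus)


# ---------------------------------------------------------------------------
# Matrices and gene tables (TSV)
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="peak_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate peak_id {dup!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cell in matrix")
    return df


def write_gene_table(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    conds = sorted({c for g in genes for c in g.expression})
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\t" + "\t".join(conds) + "\n")
        for g in genes:
            vals = "\t".join(repr(float(g.expression.get(c, 0.0))) for c in conds)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{vals}\n")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "tss", "strand"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    conds = [c for c in df.columns if c not in required]
    genes = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        genes.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                chrom=str(d["chrom"]),
                tss=int(d["tss"]),
                strand=str(d["strand"]),
                expression={c: float(d[c]) for c in conds},
            )
        )
    if len({g.gene_id for g in genes}) != len(genes):
        raise FormatError(f"{path}: duplicate gene_id")
    return genes


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
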