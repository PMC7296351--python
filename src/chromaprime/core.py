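"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open (BED convention) throughout the
package; conversion to/from other conventions happens only at I/O
boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np


class Condition(str, Enum):
    """Experimental condition of a sample.

    N = naive, T = tolerized; 0 = resting, Ag = antigen-stimulated,
    PI = PMA + calcium-ionophore stimulated; T_0M = tolerized, rested
    three weeks after the final antigen dose.
    """

    N_0 = "N_0"
    T_0 = "T_0"
    N_Ag = "N_Ag"
    T_Ag = "T_Ag"
    N_PI = "N_PI"
    T_PI = "T_PI"
    T_0M = "T_0M"

    @property
    def stimulated(self) -> bool:
        return self.value.endswith(("Ag", "PI"))

    @property
    def tolerized(self) -> bool:
        return self.value.startswith("T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass(frozen=True)
class SummitPeak:
    """A peak interval with a single-base summit (point of maximal signal)."""

    interval: GenomicInterval
    summit: int
    peak_id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end} "
                f"for peak {self.peak_id}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def check_unique_peak_ids(peaks: list[SummitPeak]) -> None:
    seen: set[str] = set()
    for p in peaks:
        if p.peak_id in seen:
            raise ValueError(f"duplicate peak_id {p.peak_id!r}")
        seen.add(p.peak_id)


def sort_peaks(peaks: list[SummitPeak]) -> list[SummitPeak]:
    return sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.peak_id))


class CutTrack:
    """Stranded per-base 5' DNase I cut counts for one sample.

    Stores one dense non-negative integer array per (chromosome, strand);
    window sums are plain slice sums.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        sample_id: str = "",
        plus: Mapping[str, np.ndarray] | None = None,
        minus: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.chrom_sizes = dict(chrom_sizes)
        self.plus: dict[str, np.ndarray] = {}
        self.minus: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            for store, src in ((self.plus, plus), (self.minus, minus)):
                if src is not None and chrom in src:
                    arr = np.asarray(src[chrom])
                    if arr.shape != (size,):
                        raise ValueError(
                            f"array length {arr.shape} != chromosome size {size} for {chrom}"
                        )
                    if np.any(arr < 0):
                        raise ValueError(f"negative cut count on {chrom}")
                    store[chrom] = arr.astype(np.int64)
                else:
                    store[chrom] = np.zeros(size, dtype=np.int64)

    @property
    def total_cuts(self) -> int:
        return int(
            sum(int(a.sum()) for a in self.plus.values())
            + sum(int(a.sum()) for a in self.minus.values())
        )

    def window_sum(self, chrom: str, start: int, end: int, strand: str = "both") -> int:
        """Total cuts in [start, end), clipped to the chromosome bounds."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        start, end = max(0, start), min(size, end)
        if end <= start:
            return 0
        total = 0
        if strand in ("both", "+"):
            total += int(self.plus[chrom][start:end].sum())
        if strand in ("both", "-"):
            total += int(self.minus[chrom][start:end].sum())
        return total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CutTrack):
            return NotImplemented
        return (
            self.chrom_sizes == other.chrom_sizes
            and all(np.array_equal(self.plus[c], other.plus[c]) for c in self.chrom_sizes)
            and all(np.array_equal(self.minus[c], other.minus[c]) for c in self.chrom_sizes)
        )


@dataclass
class GeneRecord:
    """A gene with its TSS anchor and per-condition expression values."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "."
    # condition name -> mean expression over replicates
    expression: dict[str, float] = field(default_factory=dict)
    # condition name -> list of per-replicate values (optional)
    replicates: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        for cond, v in self.expression.items():
            if v < 0:
                raise ValueError(f"negative expression for {self.gene_id} in {cond}")
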