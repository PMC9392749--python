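"""Genomic interval primitives.

All coordinates inside the package are 0-based, half-open (``[start, end)``),
on named contigs. External formats (GTF and RepeatMasker ``.out``, both
1-based inclusive) are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a strand.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: {self.start}..{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap test (>= 1 shared base)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals (strand is ignored and the
    first interval's strand is kept per merged block)."""
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct genomic bases covered by ``intervals``."""
    return sum(iv.length() for iv in merge_intervals(intervals))


def overlap_bp(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Total overlap (bp) between two merged interval sets."""
    am, bm = merge_intervals(a), merge_intervals(b)
    total = 0
    for x in am:
        for y in bm:
            total += x.overlap_len(y)
    return total
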