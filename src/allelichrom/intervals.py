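"""Genomic interval primitives and interval algebra.

All intervals are 0-based half-open (BED convention). VCF positions are
1-based and converted at the I/O boundary only. Strand is carried but
ignored by every allelic computation: pileup read counts are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, .: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.chrom == chrom and self.start <= pos0 < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= max_gap into maximal intervals.

    With max_gap=0 this merges overlapping or book-ended intervals (the
    plain genomic union); with max_gap=12500 it is the super-enhancer
    stitching rule. Gap is measured as next.start - prev.end on half-open
    coordinates, so touching intervals have gap 0.
    """
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-wise intersection of two interval sets, merged and sorted.

    Each input set is first collapsed to its union so the result is a set
    of disjoint maximal intervals covered by both inputs.
    """
    a_merged = merge_intervals(a)
    b_merged = merge_intervals(b)
    out: list[GenomicInterval] = []
    # two-pointer sweep per chromosome
    i = j = 0
    while i < len(a_merged) and j < len(b_merged):
        x, y = a_merged[i], b_merged[j]
        if x.chrom < y.chrom:
            i += 1
            continue
        if y.chrom < x.chrom:
            j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def stitch_clusters(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[list[GenomicInterval]]:
    """Group intervals into stitching clusters (chains with gaps <= max_gap).

    Returns the member intervals of each cluster in genomic order; the
    cluster span is [min start, max end]. Two intervals share a cluster iff
    a chain of intervals links them with every inter-interval gap <= max_gap
    (transitive closure of the pairwise gap relation).
    """
    clusters: list[list[GenomicInterval]] = []
    cur: list[GenomicInterval] = []
    cur_end = None
    cur_chrom = None
    for iv in sort_intervals(intervals):
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [iv]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if cur:
        clusters.append(cur)
    return clusters
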