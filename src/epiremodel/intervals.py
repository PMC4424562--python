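"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open (BED dialect) everywhere inside the
package; 1-based inputs are converted at the reader boundary.  Chromosome
names compare as exact strings ("chr1" != "1").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome."""

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

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class IntervalSet:
    """An ordered, sorted collection of intervals with optional labels.

    Sorting key is (chrom, start, end); construction sorts once, and every
    query operation is deterministic given the sorted order.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.intervals):
            raise ValueError("labels must align with intervals")
        order = sorted(
            range(len(self.intervals)), key=lambda i: self.intervals[i]
        )
        self.intervals = [self.intervals[i] for i in order]
        if self.labels is not None:
            self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_bases(self) -> int:
        return sum(len(iv) for iv in merge_intervals(self, 0))


def merge_intervals(ivset: IntervalSet | Sequence[GenomicInterval],
                    max_gap: int = 0) -> IntervalSet:
    """Merge intervals separated by at most ``max_gap`` bases.

    Output intervals are pairwise separated by more than ``max_gap``; covered
    bases are preserved, extended only across gaps of size <= max_gap.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sorted(ivset if isinstance(ivset, (list, tuple)) else ivset.intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and \
                iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged)


def overlap_pairs(a: IntervalSet, b: IntervalSet) -> list[tuple[int, int]]:
    """All (index_a, index_b) pairs with >= 1 bp overlap, sorted-sweep.

    Symmetric in content under argument swap (pairs transpose).
    """
    pairs: list[tuple[int, int]] = []
    j0 = 0
    for i, iva in enumerate(a.intervals):
        # b[j0] can never overlap this or any later a-interval: a is sorted,
        # so all later starts on this chrom are >= iva.start
        while j0 < len(b) and (
            b[j0].chrom < iva.chrom
            or (b[j0].chrom == iva.chrom and b[j0].end <= iva.start)
        ):
            j0 += 1
        for j in range(j0, len(b)):
            ivb = b[j]
            if ivb.chrom > iva.chrom or (
                ivb.chrom == iva.chrom and ivb.start >= iva.end
            ):
                break
            if iva.overlaps(ivb):
                pairs.append((i, j))
    return pairs


def overlaps_any(query: IntervalSet, feature: IntervalSet) -> list[bool]:
    """For each query interval, whether it overlaps >= 1 feature interval."""
    hit = [False] * len(query)
    for i, _ in overlap_pairs(query, feature):
        hit[i] = True
    return hit
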