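"""Genomic interval primitives shared across the package.

All coordinates are 0-based, half-open ``[start, end)``. GTF input (1-based,
closed) is converted on ingest; BED/narrowPeak/rMATS coordinates are native.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

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
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalIndex:
    """Per-chromosome interval tree for ≥1-base overlap queries."""

    _trees: dict = field(default_factory=dict)

    @classmethod
    def build(cls, intervals: Iterable[GenomicInterval]) -> "IntervalIndex":
        idx = cls()
        for iv in intervals:
            idx.add(iv)
        return idx

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlap(query.start, query.end))

    def query(self, query: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits
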