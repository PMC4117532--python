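"""Genomic interval algebra.

Intervals are 0-based half-open internally.  BED I/O keeps that convention;
GFF3 and user-facing coordinate reports are 1-based inclusive (see
:attr:`GenomicInterval.start1` / :attr:`GenomicInterval.end1`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .exceptions import InputError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise InputError(f"invalid strand {self.strand!r}")

    # -- coordinate conventions -------------------------------------------
    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GFF3 / printed style)."""
        return cls(chrom, start1 - 1, end1, strand)

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # printed 1-based, like genome browsers
        return f"{self.chrom}:{self.start1}-{self.end1}"


@dataclass(frozen=True)
class FeatureDistance:
    """Distance between two same-chromosome intervals.

    ``bp`` is 0 whenever the intervals touch or overlap under the
    ``edge_gap`` convention; ``overlaps`` flags a >= 1 bp overlap regardless
    of convention.
    """

    bp: int
    overlaps: bool
    convention: str


def distance_to_feature(
    repeat: GenomicInterval,
    feature: GenomicInterval,
    convention: str = "start_to_start",
) -> FeatureDistance:
    """Distance from ``repeat`` to ``feature``.

    ``start_to_start`` reproduces printed browser-style offsets
    (|feature.start − repeat.start|, identical in 0- and 1-based terms);
    ``edge_gap`` counts the bases strictly between the intervals, 0 if they
    touch or overlap.
    """
    if repeat.chrom != feature.chrom:
        raise InputError(
            f"intervals on different chromosomes: {repeat.chrom} vs {feature.chrom}"
        )
    overlaps = repeat.overlaps(feature)
    if convention == "start_to_start":
        bp = abs(feature.start - repeat.start)
    elif convention == "edge_gap":
        bp = 0 if overlaps else max(
            0, max(repeat.start, feature.start) - min(repeat.end, feature.end)
        )
    else:
        raise InputError(f"unknown distance convention {convention!r}")
    return FeatureDistance(bp=bp, overlaps=overlaps, convention=convention)


class IntervalIndex:
    """Per-chromosome interval tree supporting overlap and proximity queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._items.append(iv)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def overlapping(self, q: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(q.start, q.end))

    def within(self, q: GenomicInterval, max_gap: int) -> list[GenomicInterval]:
        """Intervals whose edge gap to ``q`` is <= ``max_gap`` (overlap → gap 0)."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        # widen by 1 so features at exactly max_gap are retrieved, then filter
        lo = max(0, q.start - max_gap - 1)
        hits = sorted(hit.data for hit in tree.overlap(lo, q.end + max_gap + 1))
        return [
            iv for iv in hits
            if distance_to_feature(q, iv, "edge_gap").bp <= max_gap
        ]


def overlaps_any(q: GenomicInterval, track: Sequence[GenomicInterval] | IntervalIndex) -> bool:
    """True iff ``q`` overlaps (>= 1 bp, half-open semantics) any track interval."""
    if isinstance(track, IntervalIndex):
        return bool(track.overlapping(q))
    return any(q.overlaps(iv) for iv in track)
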