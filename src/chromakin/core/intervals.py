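"""Genomic coordinate primitives.

All coordinates are 0-based half-open (BED convention). GTF input is
converted on read. Adjacent (touching) half-open intervals have distance 0
but do not overlap for merge purposes: merging requires at least one shared
base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class CoordinateError(ValueError):
    """An interval violates the coordinate invariants."""


class DistanceError(ValueError):
    """Distance requested between intervals on different chromosomes."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"start < 0: {self!r}")
        if self.end <= self.start:
            raise CoordinateError(f"end <= start: {self!r}")
        if self.strand not in STRANDS:
            raise CoordinateError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 base on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def oriented_strand(self) -> str:
        """Strand with '.' coerced to '+' for orientation-sensitive work."""
        if self.strand == ".":
            log.warning("strand '.' treated as '+' for %r", self)
            return "+"
        return self.strand

    def expanded(self, flank: int) -> "GenomicInterval":
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bases between two intervals; 0 if they overlap or touch.

    Raises :class:`DistanceError` for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        raise DistanceError(f"{a.chrom} vs {b.chrom}")
    if a.overlaps(b):
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def point_interval_distance(chrom: str, pos: int, iv: GenomicInterval) -> int:
    """Distance from a point to an interval; 0 if the point lies inside."""
    if chrom != iv.chrom:
        raise DistanceError(f"{chrom} vs {iv.chrom}")
    if iv.contains(pos):
        return 0
    if pos < iv.start:
        return iv.start - pos
    return pos - iv.end + 1


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[tuple[GenomicInterval, list[int]]]:
    """Transitive closure of >=1-bp overlap.

    Returns merged intervals paired with the indices (into the input order)
    of their members. Touching intervals ([a,b) and [b,c)) are NOT merged.
    Output is sorted by (chrom, start); merging is input-order invariant.
    """
    indexed = sorted(enumerate(intervals), key=lambda t: (t[1].chrom, t[1].start, t[1].end))
    merged: list[tuple[GenomicInterval, list[int]]] = []
    for idx, iv in indexed:
        if merged:
            cur, members = merged[-1]
            if cur.chrom == iv.chrom and iv.start < cur.end:
                if iv.end > cur.end:
                    cur = GenomicInterval(cur.chrom, cur.start, iv.end, cur.strand)
                merged[-1] = (cur, members + [idx])
                continue
        merged.append((GenomicInterval(iv.chrom, iv.start, iv.end, "."), [idx]))
    return merged


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcription start/termination sites and exons."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = None
        for ex in sorted(self.exons, key=lambda e: e.start):
            if ex.chrom != self.interval.chrom:
                raise CoordinateError(f"exon off-chromosome in {self.gene_id}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise CoordinateError(f"exon outside gene body in {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise CoordinateError(f"overlapping exons in {self.gene_id}")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.oriented_strand()

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def exon_kb(self) -> float:
        """Total exonic length in kilobases (gene body if no exons given)."""
        if self.exons:
            return sum(len(e) for e in self.exons) / 1000.0
        return len(self.interval) / 1000.0


def nearest_gene_distance(chrom: str, pos: int, gene: GeneModel) -> int:
    """min(|pos - TSS|, |pos - TTS|); 0 when pos is inside the gene body."""
    if chrom != gene.interval.chrom:
        raise DistanceError(f"{chrom} vs {gene.interval.chrom}")
    if gene.interval.contains(pos):
        return 0
    return min(abs(pos - gene.tss), abs(pos - gene.tts))


def sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def validate_sorted_disjoint(intervals: Sequence[GenomicInterval]) -> None:
    """Raise if intervals (assumed same track) overlap each other."""
    by_chrom: dict[str, int] = {}
    for iv in sorted(intervals, key=sort_key):
        last = by_chrom.get(iv.chrom, -1)
        if iv.start < last:
            raise CoordinateError(f"overlapping records at {iv}")
        by_chrom[iv.chrom] = iv.end
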