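"""Genomic intervals in 1-based inclusive coordinates.

The whole package uses the UCSC-browser / PennCNV display convention:
``start`` and ``end`` are both 1-based and inclusive, so a segment's length
is ``end - start + 1``.  BED input/output converts at the boundary
(:mod:`cnvpipe.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the ``chrN`` form (``16`` -> ``chr16``)."""
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval (1-based, inclusive on both ends)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # chr16:21950000-22430000
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrN:start-end`` (commas in numbers tolerated)."""
        try:
            chrom, span = text.split(":")
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse interval {text!r}") from exc


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals; output sorted per chromosome.

    Book-ended means end(A) + 1 == start(B): adjacent bases form one run.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_overlap_bp(
    query: GenomicInterval, track: Sequence[GenomicInterval]
) -> int:
    """Bases of ``query`` covered by the union of ``track`` intervals."""
    return sum(query.overlap_bp(iv) for iv in merge_intervals(track) if iv.chrom == query.chrom) if track else 0
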