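"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)``. Strand is ``"+"``,
``"-"`` or ``"."`` (unstranded). These conventions are applied uniformly:
GTF input (1-based inclusive) is converted on read, BED output is written
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Ordering is lexicographic on (contig, start, end, strand), which makes
    sorted lists of intervals coordinate-sorted within a contig.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap on the same contig (strand is not compared)."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def jaccard(self, other: "GenomicInterval") -> float:
        """Interval Jaccard index; 0 if on different contigs."""
        if self.contig != other.contig:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        union = (self.end - self.start) + (other.end - other.start) - inter
        return inter / union


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_adjacent: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping intervals into maximal disjoint ones.

    Intervals are grouped by (contig, strand). With ``merge_adjacent``,
    book-ended intervals (end == start) are coalesced as well, consistent
    with half-open adjacency.
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.contig, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for (contig, strand), ivs in by_key.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            gap_ok = iv.start <= cur_e if merge_adjacent else iv.start < cur_e
            if gap_ok:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(contig, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(contig, cur_s, cur_e, strand))
    out.sort()
    return out


def overlaps_any(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask: does each query interval overlap (>=1 bp) any subject?

    Contig and strand must both match. Sorted-sweep on numpy arrays.
    """
    mask = np.zeros(len(query), dtype=bool)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in subject:
        by_key.setdefault((iv.contig, iv.strand), []).append((iv.start, iv.end))
    prepared = {}
    for key, pairs in by_key.items():
        arr = np.array(sorted(pairs), dtype=np.int64)
        # running max of ends lets a single searchsorted answer "any overlap"
        starts = arr[:, 0]
        maxend = np.maximum.accumulate(arr[:, 1])
        prepared[key] = (starts, maxend)
    for i, iv in enumerate(query):
        got = prepared.get((iv.contig, iv.strand))
        if got is None:
            continue
        starts, maxend = got
        k = np.searchsorted(starts, iv.end)  # subjects with start < iv.end
        if k > 0 and maxend[k - 1] > iv.start:
            mask[i] = True
    return mask
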