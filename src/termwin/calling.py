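"""Two-tier broad-enrichment calling and cross-study consensus.

The caller reproduces the classic broad-peak strategy used on bedGraph
signal (macs2 bdgbroadcall): a high "peak" cutoff defines strong regions
(with small internal gaps closed), a low "link" cutoff defines weak
regions, and strong regions that are bridged by weak signal within a
larger linking gap are joined. Regions shorter than a minimum length are
dropped. Thresholds are strictly-greater comparisons (value > cutoff).

Consensus across two independent studies keeps only regions that overlap
(>= 1 bp) a region from the other study, then merges the retained pool
into maximal disjoint termination windows (book-ended intervals are
coalesced, consistent with half-open adjacency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack, ExtensionParams, extend_signal, mean_tracks
from .intervals import GenomicInterval, merge_intervals, overlaps_any

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BroadCallParams:
    """Thresholds of the two-tier caller (bdgbroadcall defaults)."""

    cutoff_peak: float = 2.0
    cutoff_link: float = 1.0
    min_length: int = 200
    max_gap_within: int = 30
    max_gap_link: int = 800

    def __post_init__(self) -> None:
        if not (self.cutoff_peak >= self.cutoff_link > 0):
            raise ValueError("require cutoff_peak >= cutoff_link > 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (self.max_gap_link >= self.max_gap_within >= 0):
            raise ValueError("require max_gap_link >= max_gap_within >= 0")


@dataclass(frozen=True)
class EnrichedRegion:
    interval: GenomicInterval
    source_label: str = ""


@dataclass
class TerminationWindowSet:
    """Sorted, per-strand disjoint consensus windows with provenance."""

    windows: list[GenomicInterval]
    provenance: list[list[EnrichedRegion]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)


def _runs_above(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Maximal runs of bases with value > cutoff, as (start, end) pairs."""
    runs: list[tuple[int, int]] = []
    for s, e, v in zip(starts, ends, values):
        if v > cutoff:
            if runs and runs[-1][1] == s:
                runs[-1] = (runs[-1][0], int(e))
            else:
                runs.append((int(s), int(e)))
    return runs


def _close_gaps(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    out = [runs[0]]
    for s, e in runs[1:]:
        if s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def call_broad_regions(
    track: CoverageTrack,
    params: BroadCallParams = BroadCallParams(),
    source_label: str = "",
) -> list[EnrichedRegion]:
    """Two-tier broad-region calling on one run-length track.

    1. strong regions: runs of value > cutoff_peak, internal gaps
       <= max_gap_within closed;
    2. link regions: runs of value > cutoff_link, gaps <= max_gap_link
       closed;
    3. strong regions inside the same link region are joined; the emitted
       region spans from the first to the last joined strong region (the
       weak signal connecting them is thereby included);
    4. regions shorter than min_length are discarded.
    """
    regions: list[EnrichedRegion] = []
    for contig in track.contigs:
        starts, ends, values = track.segments(contig)
        strong = _close_gaps(
            _runs_above(starts, ends, values, params.cutoff_peak),
            params.max_gap_within,
        )
        if not strong:
            continue
        link = _close_gaps(
            _runs_above(starts, ends, values, params.cutoff_link),
            params.max_gap_link,
        )
        link_starts = np.array([s for s, _ in link], dtype=np.int64)
        # every strong base exceeds cutoff_link, and max_gap_within <=
        # max_gap_link, so each strong region lies inside exactly one link
        # region: locate it by start position
        groups: dict[int, list[tuple[int, int]]] = {}
        for s, e in strong:
            idx = int(np.searchsorted(link_starts, s, side="right")) - 1
            groups.setdefault(idx, []).append((s, e))
        for idx in sorted(groups):
            members = groups[idx]
            lo = members[0][0]
            hi = members[-1][1]
            if hi - lo >= params.min_length:
                regions.append(
                    EnrichedRegion(
                        GenomicInterval(contig, lo, hi, track.strand), source_label
                    )
                )
    regions.sort(key=lambda r: r.interval)
    return regions


def consensus(
    regions_a: Sequence[EnrichedRegion],
    regions_b: Sequence[EnrichedRegion],
    merge_adjacent: bool = True,
) -> TerminationWindowSet:
    """Cross-study consensus: keep cross-overlapping regions, then merge."""
    ivs_a = [r.interval for r in regions_a]
    ivs_b = [r.interval for r in regions_b]
    keep_a = overlaps_any(ivs_a, ivs_b)
    keep_b = overlaps_any(ivs_b, ivs_a)
    retained = [r for r, k in zip(regions_a, keep_a) if k] + [
        r for r, k in zip(regions_b, keep_b) if k
    ]
    return _merge_with_provenance(retained, merge_adjacent)


def _merge_with_provenance(
    retained: Sequence[EnrichedRegion], merge_adjacent: bool = True
) -> TerminationWindowSet:
    windows = merge_intervals([r.interval for r in retained], merge_adjacent)
    provenance: list[list[EnrichedRegion]] = []
    for w in windows:
        provenance.append(
            [
                r
                for r in retained
                if r.interval.strand == w.strand and r.interval.overlaps(w)
            ]
        )
    return TerminationWindowSet(windows, provenance)


def call_termination_windows(
    replicate_sets: Sequence[Sequence[CoverageTrack]],
    extension: ExtensionParams = ExtensionParams(),
    params: BroadCallParams = BroadCallParams(),
    set_labels: Sequence[str] | None = None,
) -> TerminationWindowSet:
    """Full window definition for one strand.

    Per replicate set (study): average replicates, extend the signal,
    call broad regions. Consensus across studies then keeps regions
    overlapping a region from at least one other study and merges them.
    Requires >= 2 sets — a single study cannot form a consensus.
    """
    if len(replicate_sets) < 2:
        raise ValueError(
            "consensus requires >= 2 replicate sets (independent studies)"
        )
    if set_labels is None:
        set_labels = [f"set{i + 1}" for i in range(len(replicate_sets))]
    per_set: list[list[EnrichedRegion]] = []
    for label, tracks in zip(set_labels, replicate_sets):
        avg = mean_tracks(list(tracks))
        ext = extend_signal(avg, extension)
        regs = call_broad_regions(ext, params, source_label=label)
        logger.info("%s: %d enriched regions", label, len(regs))
        per_set.append(regs)
    if len(per_set) == 2:
        return consensus(per_set[0], per_set[1])
    retained: list[EnrichedRegion] = []
    for i, regs in enumerate(per_set):
        others = [r.interval for j, rs in enumerate(per_set) if j != i for r in rs]
        keep = overlaps_any([r.interval for r in regs], others)
        retained.extend(r for r, k in zip(regs, keep) if k)
    return _merge_with_provenance(retained)


def windows_to_bed(windows: TerminationWindowSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows.windows):
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\tTW{i + 1:05d}\t0\t{w.strand}\n")
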