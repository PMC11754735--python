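"""Strand-specific coverage tracks: bedGraph I/O, averaging, extension, sums.

A :class:`CoverageTrack` holds one strand's signal as per-contig run-length
segments (start, end, value); absent positions are 0. Values are doubles.
Operations that need base resolution densify one contig at a time, which is
fine for the contig sizes this package targets (simulated genomes and
per-chromosome processing of real data).

The signal-extension step reproduces a common preprocessing of
single-nucleotide nascent-transcription data (mNET-seq and relatives):
each recorded polymerase position is inflated to a read-length interval
(default 150 bp) before peak calling, turning a sparse point process into
read-pileup-like coverage.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

Segments = tuple[np.ndarray, np.ndarray, np.ndarray]  # starts, ends, values


@dataclass
class ExtensionParams:
    """How to inflate single-base signal to read-sized intervals.

    anchor "five_prime": the recorded base is the 5' end of the interval in
    strand orientation — [p, p+L) on +, (p-L, p] on -. anchor "center":
    the interval is centered on the recorded base.
    """

    length_bp: int = 150
    anchor: Literal["five_prime", "center"] = "five_prime"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.anchor not in ("five_prime", "center"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


class CoverageTrack:
    """Run-length, strand-specific, non-negative coverage."""

    def __init__(self, strand: str, assembly_tag: str = "") -> None:
        if strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.strand = strand
        self.assembly_tag = assembly_tag
        self._segments: dict[str, Segments] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_segments(
        cls,
        strand: str,
        segments: dict[str, Iterable[tuple[int, int, float]]],
        assembly_tag: str = "",
    ) -> "CoverageTrack":
        track = cls(strand, assembly_tag)
        for contig, segs in segments.items():
            arr = sorted(segs)
            if not arr:
                continue
            starts = np.array([s for s, _, _ in arr], dtype=np.int64)
            ends = np.array([e for _, e, _ in arr], dtype=np.int64)
            values = np.array([v for _, _, v in arr], dtype=np.float64)
            track._set_contig(contig, starts, ends, values)
        return track

    def _set_contig(
        self, contig: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> None:
        if np.any(values < 0):
            raise ValueError(f"negative coverage values on {contig}")
        if np.any(ends <= starts):
            raise ValueError(f"empty or inverted segment on {contig}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping segments on {contig}")
        starts, ends, values = _coalesce(starts, ends, values)
        if len(starts):
            self._segments[contig] = (starts, ends, values)

    @classmethod
    def from_dense(
        cls, strand: str, dense: dict[str, np.ndarray], assembly_tag: str = ""
    ) -> "CoverageTrack":
        track = cls(strand, assembly_tag)
        for contig, arr in dense.items():
            starts, ends, values = _rle_encode(np.asarray(arr, dtype=np.float64))
            if len(starts):
                track._set_contig(contig, starts, ends, values)
        return track

    # -- views ------------------------------------------------------------

    @property
    def contigs(self) -> list[str]:
        return sorted(self._segments)

    def segments(self, contig: str) -> Segments:
        empty = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
        )
        return self._segments.get(contig, empty)

    def max_end(self, contig: str) -> int:
        starts, ends, _ = self.segments(contig)
        return int(ends[-1]) if len(ends) else 0

    def to_dense(self, contig: str, length: int | None = None) -> np.ndarray:
        starts, ends, values = self.segments(contig)
        n = length if length is not None else (int(ends[-1]) if len(ends) else 0)
        out = np.zeros(n, dtype=np.float64)
        for s, e, v in zip(starts, ends, values):
            if s >= n:
                break
            out[s : min(e, n)] = v
        return out

    def total(self) -> float:
        """Sum of per-base values over all contigs."""
        tot = 0.0
        for starts, ends, values in self._segments.values():
            tot += float(np.sum((ends - starts) * values))
        return tot

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.strand != other.strand or set(self._segments) != set(other._segments):
            return False
        for contig in self._segments:
            for a, b in zip(self._segments[contig], other._segments[contig]):
                if not np.array_equal(a, b):
                    return False
        return True


def _coalesce(starts, ends, values) -> Segments:
    """Drop zero segments; merge adjacent equal-valued segments."""
    keep = values != 0
    starts, ends, values = starts[keep], ends[keep], values[keep]
    if len(starts) == 0:
        return starts, ends, values
    out_s, out_e, out_v = [starts[0]], [ends[0]], [values[0]]
    for s, e, v in zip(starts[1:], ends[1:], values[1:]):
        if s == out_e[-1] and v == out_v[-1]:
            out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
            out_v.append(v)
    return (
        np.array(out_s, dtype=np.int64),
        np.array(out_e, dtype=np.int64),
        np.array(out_v, dtype=np.float64),
    )


def _rle_encode(arr: np.ndarray) -> Segments:
    if arr.size == 0:
        return _coalesce(
            np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)
        )
    change = np.flatnonzero(np.diff(arr) != 0) + 1
    starts = np.concatenate([[0], change]).astype(np.int64)
    ends = np.concatenate([change, [arr.size]]).astype(np.int64)
    values = arr[starts]
    return _coalesce(starts, ends, values)


# -- I/O -------------------------------------------------------------------


def read_bedgraph(path: str, strand: str, assembly_tag: str = "") -> CoverageTrack:
    """Read a bedGraph (plain or gzip) into a run-length track.

    Unsorted input is sorted internally with a warning; overlapping
    segments or negative values are errors.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["contig", "start", "end", "value"],
        dtype={"contig": str},
        compression="infer",
        skiprows=_count_header_lines(path),
    )
    track = CoverageTrack(strand, assembly_tag)
    if df.empty:
        return track
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    for contig, sub in df.groupby("contig", sort=True):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        values = sub["value"].to_numpy(np.float64)
        if np.any(starts[1:] < starts[:-1]):
            warnings.warn(f"{path}: unsorted bedGraph on {contig}; sorting")
            order = np.lexsort((ends, starts))
            starts, ends, values = starts[order], ends[order], values[order]
        track._set_contig(contig, starts, ends, values)
    return track


def _count_header_lines(path: str) -> int:
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(track: CoverageTrack, path: str, precision: int = 6) -> None:
    """Write non-zero segments; values with up to `precision` significant digits."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for contig in track.contigs:
            starts, ends, values = track.segments(contig)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{contig}\t{s}\t{e}\t{v:.{precision}g}\n")


# -- operations ------------------------------------------------------------


def mean_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean; absent positions count as 0."""
    if not tracks:
        raise ValueError("mean_tracks requires at least one track")
    strands = {t.strand for t in tracks}
    if len(strands) > 1:
        raise ValueError(f"mixed strands in mean_tracks: {sorted(strands)}")
    tags = {t.assembly_tag for t in tracks}
    if len(tags) > 1:
        raise ValueError(f"mixed assembly tags in mean_tracks: {sorted(tags)}")
    out = CoverageTrack(tracks[0].strand, tracks[0].assembly_tag)
    contigs = sorted({c for t in tracks for c in t.contigs})
    k = len(tracks)
    for contig in contigs:
        # breakpoint sweep over the union of segment boundaries
        events: list[np.ndarray] = []
        deltas: list[np.ndarray] = []
        for t in tracks:
            starts, ends, values = t.segments(contig)
            events.append(starts)
            deltas.append(values)
            events.append(ends)
            deltas.append(-values)
        pos = np.concatenate(events)
        dlt = np.concatenate(deltas)
        order = np.argsort(pos, kind="stable")
        pos, dlt = pos[order], dlt[order]
        upos, inverse = np.unique(pos, return_inverse=True)
        level = np.zeros(len(upos), dtype=np.float64)
        np.add.at(level, inverse, dlt)
        level = np.cumsum(level) / k
        level[np.isclose(level, 0.0, atol=1e-12)] = 0.0
        starts, ends, values = upos[:-1], upos[1:], level[:-1]
        keep = values != 0
        out._set_contig(contig, starts[keep], ends[keep], values[keep])
    return out


def extend_signal(
    track: CoverageTrack, params: ExtensionParams = ExtensionParams()
) -> CoverageTrack:
    """Inflate each base's value over a length_bp interval and sum.

    Each base p carrying value v contributes v to every base of its
    anchored interval; contributions add. Intervals are clipped at
    position 0 (minus strand, five_prime anchor extends leftward).
    """
    L = params.length_bp
    out = CoverageTrack(track.strand, track.assembly_tag)
    for contig in track.contigs:
        n = track.max_end(contig)
        if params.anchor == "five_prime":
            if track.strand == "+":
                lead, tail = 0, L - 1
            else:
                lead, tail = L - 1, 0
        else:
            # centered interval [p - shift, p - shift + L), strand-independent
            shift = (L - 1) // 2
            lead, tail = shift, L - 1 - shift
        dense = track.to_dense(contig, n)
        # moving-sum via prefix sums: ext[x] = sum f[p] for p in [x-tail, x+lead]
        # with + strand five_prime: contribution window [p, p+L) means
        # ext[x] = sum_{p in (x-L, x]} f[p]
        csum = np.concatenate([[0.0], np.cumsum(dense)])
        m = n + tail  # rightmost covered base index + 1
        x = np.arange(m)
        lo = np.clip(x - tail, 0, n)
        hi = np.clip(x + lead + 1, 0, n)
        ext = csum[hi] - csum[lo]
        ext[np.isclose(ext, 0.0, atol=1e-12)] = 0.0
        starts, ends, values = _rle_encode(ext)
        if len(starts):
            out._set_contig(contig, starts, ends, values)
    return out


def window_sum(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of per-base values over [start, end)."""
    if interval.strand not in (track.strand, "."):
        raise ValueError(
            f"interval strand {interval.strand} does not match track {track.strand}"
        )
    if interval.contig not in track._segments:
        if interval.contig not in track.contigs:
            warnings.warn(f"interval contig {interval.contig} not in track; sum=0")
        return 0.0
    starts, ends, values = track.segments(interval.contig)
    lo = np.maximum(starts, interval.start)
    hi = np.minimum(ends, interval.end)
    overlap = np.clip(hi - lo, 0, None)
    return float(np.sum(overlap * values))


def binned_profile(
    track: CoverageTrack, interval: GenomicInterval, n_bins: int
) -> np.ndarray:
    """Mean per-base value in n_bins equal subdivisions, 5'->3' oriented.

    Bins may be fractional: each bin mean is the integral of the step
    function over the (real-valued) bin divided by the bin width. Minus
    strand output is reversed so index 0 is the 5' bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    starts, ends, values = track.segments(interval.contig)
    width = (interval.end - interval.start) / n_bins
    edges = interval.start + width * np.arange(n_bins + 1)
    edges[-1] = interval.end  # guard rounding
    integ = _step_integral(starts, ends, values, edges)
    means = np.diff(integ) / width
    strand = interval.strand if interval.strand != "." else track.strand
    if strand == "-":
        means = means[::-1]
    return means


def _step_integral(starts, ends, values, points: np.ndarray) -> np.ndarray:
    """Integral of the run-length step function over (-inf, t] for each t."""
    if len(starts) == 0:
        return np.zeros(len(points))
    seglen = (ends - starts).astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(seglen * values)])
    out = np.empty(len(points))
    for i, t in enumerate(points):
        j = int(np.searchsorted(ends, t, side="left"))  # first segment with end > t
        base = cum[j]
        if j < len(starts) and t > starts[j]:
            base += (t - starts[j]) * values[j]
        out[i] = base
    return out
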