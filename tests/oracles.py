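"""Independent brute-force reference implementations used only by tests.

Each oracle works per base (or per pair) with plain Python loops and no
shared code with the package's implementations. They are deliberately
slow and obvious.
"""

from __future__ import annotations

import numpy as np

from termwin.annotation import GeneModel
from termwin.coverage import CoverageTrack
from termwin.intervals import GenomicInterval


def dense_of(track: CoverageTrack, contig: str, n: int) -> np.ndarray:
    out = np.zeros(n)
    starts, ends, values = track.segments(contig)
    for s, e, v in zip(starts, ends, values):
        for p in range(s, min(e, n)):
            out[p] = v
    return out


def brute_extend(dense: np.ndarray, length: int, strand: str) -> np.ndarray:
    """Per-base accumulation of 5'-anchored read-sized intervals."""
    n = len(dense)
    out = np.zeros(n + length)
    for p in range(n):
        v = dense[p]
        if v == 0:
            continue
        if strand == "+":
            lo, hi = p, p + length
        else:
            lo, hi = max(p - length + 1, 0), p + 1
        for x in range(lo, hi):
            out[x] += v
    return out


def brute_broadcall(
    dense: np.ndarray,
    cutoff_peak: float,
    cutoff_link: float,
    min_length: int,
    max_gap_within: int,
    max_gap_link: int,
) -> list[tuple[int, int]]:
    """Per-base two-tier broad calling.

    strong runs (> cutoff_peak) with gaps <= max_gap_within closed; link
    runs (> cutoff_link) with gaps <= max_gap_link closed; strong runs in
    the same link run are joined (emitted region spans first to last);
    regions shorter than min_length dropped.
    """

    def runs(mask: list[bool]) -> list[list[int]]:
        found, cur = [], None
        for i, m in enumerate(mask):
            if m and cur is None:
                cur = i
            elif not m and cur is not None:
                found.append([cur, i])
                cur = None
        if cur is not None:
            found.append([cur, len(mask)])
        return found

    def close(rr: list[list[int]], gap: int) -> list[list[int]]:
        out: list[list[int]] = []
        for s, e in rr:
            if out and s - out[-1][1] <= gap:
                out[-1][1] = e
            else:
                out.append([s, e])
        return out

    strong = close(runs([v > cutoff_peak for v in dense]), max_gap_within)
    link = close(runs([v > cutoff_link for v in dense]), max_gap_link)
    regions = []
    for ls, le in link:
        members = [(s, e) for s, e in strong if s >= ls and e <= le]
        if not members:
            continue
        lo, hi = members[0][0], members[-1][1]
        if hi - lo >= min_length:
            regions.append((lo, hi))
    return regions


def brute_consensus(
    regions_a: list[tuple[int, int]], regions_b: list[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    """Per-base set union of cross-overlapping regions, then maximal runs.

    Half-open adjacency means book-ended retained regions fuse into one
    run automatically.
    """

    def overlaps(x, y):
        return x[0] < y[1] and y[0] < x[1]

    keep = [r for r in regions_a if any(overlaps(r, s) for s in regions_b)]
    keep += [r for r in regions_b if any(overlaps(r, s) for s in regions_a)]
    mask = [False] * n
    for s, e in keep:
        for p in range(s, e):
            mask[p] = True
    out, cur = [], None
    for i, m in enumerate(mask):
        if m and cur is None:
            cur = i
        elif not m and cur is not None:
            out.append((cur, i))
            cur = None
    if cur is not None:
        out.append((cur, n))
    return out


def brute_select(genes: list[GeneModel], isolation_bp: int) -> list[str]:
    """O(n^2) all-pairs preselection (protein_coding retained set)."""
    kept = []
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        ok = True
        for h in genes:
            if h.gene_id == g.gene_id:
                continue
            if h.contig != g.contig or h.strand != g.strand:
                continue
            if h.interval.start < g.interval.end and g.interval.start < h.interval.end:
                ok = False
                break
            if g.strand == "+":
                dist = h.tss - g.pas
            else:
                dist = g.pas - h.tss
            if 0 <= dist < isolation_bp:
                ok = False
                break
        if ok:
            kept.append(g.gene_id)
    return sorted(kept)


def brute_binned_means(
    dense: np.ndarray, start: int, end: int, n_bins: int, strand: str
) -> np.ndarray:
    """Fractional-bin means via explicit per-base overlap weights."""
    width = (end - start) / n_bins
    out = np.zeros(n_bins)
    for b in range(n_bins):
        lo = start + b * width
        hi = start + (b + 1) * width
        acc = 0.0
        for p in range(int(np.floor(lo)), int(np.ceil(hi))):
            w = min(hi, p + 1) - max(lo, p)
            if w > 0 and 0 <= p < len(dense):
                acc += dense[p] * w
        out[b] = acc / width
    if strand == "-":
        out = out[::-1]
    return out
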