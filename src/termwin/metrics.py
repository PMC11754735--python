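"""Characterization metrics: metagene matrices, unit-max scaling,
PAS/TSS log2 ratios, and activity-quintile profiles.

The metagene follows the scale-regions convention: each region's body is
rescaled to a fixed number of equal bins (bin value = mean per-base
signal over the, possibly fractional, bin), flanks are binned at fixed
width, and minus-strand rows are reversed so every row reads 5'->3'.
The column mean of the matrix is the average profile.

Unit-max scaling mimics the common two-pass normalization of published
metagene figures: compute each track's average profile, take
1 / max(profile) as the track's scale factor, then rebuild the matrix
from the scaled track. Binning is linear in the signal, so rebuilding
equals multiplying the matrix by the factor; the factor is retained so
callers can scale the underlying track for other displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, derive_regions
from .coverage import CoverageTrack, binned_profile, window_sum
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class MetageneSettings:
    """Geometry of a scale-regions matrix.

    Defaults mirror a typical published layout: 100 body bins with 5 kb
    flanks at 10 bp resolution; use flank_bp=2000 for tighter views.
    """

    n_body_bins: int = 100
    flank_bp: int = 5000
    bin_bp: int = 10

    def __post_init__(self) -> None:
        if self.n_body_bins < 1 or self.bin_bp < 1 or self.flank_bp < 0:
            raise ValueError("invalid metagene geometry")
        if self.flank_bp % self.bin_bp:
            raise ValueError("flank_bp must be a multiple of bin_bp")

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.bin_bp

    @property
    def n_bins(self) -> int:
        return self.n_body_bins + 2 * self.n_flank_bins


@dataclass
class MetageneProfile:
    matrix: np.ndarray  # regions x bins
    settings: MetageneSettings
    label: str = ""
    scale_factor: Optional[float] = None

    @property
    def profile(self) -> np.ndarray:
        """Column-mean average profile."""
        return self.matrix.mean(axis=0)


def metagene(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    settings: MetageneSettings = MetageneSettings(),
    label: str = "",
) -> MetageneProfile:
    """Scale-regions matrix of one track over many regions."""
    if not regions:
        raise ValueError("metagene requires at least one region")
    nf = settings.n_flank_bins
    rows = np.empty((len(regions), settings.n_bins), dtype=np.float64)
    for i, region in enumerate(regions):
        strand = region.strand if region.strand != "." else track.strand
        body = binned_profile(track, region, settings.n_body_bins)
        if nf:
            up = _flank_bins(track, region, strand, settings, upstream=True)
            dn = _flank_bins(track, region, strand, settings, upstream=False)
        else:
            up = dn = np.empty(0)
        rows[i] = np.concatenate([up, body, dn])
    return MetageneProfile(rows, settings, label=label)


def _flank_bins(
    track: CoverageTrack,
    region: GenomicInterval,
    strand: str,
    settings: MetageneSettings,
    upstream: bool,
) -> np.ndarray:
    """Fixed-width flank bins, 5'->3' in transcription direction.

    Bins falling (partly) before position 0 treat the missing bases as 0,
    so flank geometry stays aligned at contig edges.
    """
    nf, w, flank = settings.n_flank_bins, settings.bin_bp, settings.flank_bp
    out = np.empty(nf, dtype=np.float64)
    for j in range(nf):
        if strand == "+":
            a = (region.start - flank + j * w) if upstream else (region.end + j * w)
        else:  # 5'->3' runs right to left genomically
            a = (
                (region.end + flank - (j + 1) * w)
                if upstream
                else (region.start - (j + 1) * w)
            )
        lo, hi = max(a, 0), max(a + w, 0)
        if hi <= lo:
            out[j] = 0.0
        else:
            out[j] = window_sum(track, GenomicInterval(region.contig, lo, hi, strand)) / w
    return out


def unit_max_scale(profiles: Sequence[MetageneProfile]) -> list[MetageneProfile]:
    """Scale each track's matrix so its average profile peaks at 1."""
    out = []
    for p in profiles:
        peak = float(np.max(p.profile))
        if peak <= 0:
            raise ValueError(
                f"unit-max scaling undefined for track {p.label!r}: profile max is 0"
            )
        factor = 1.0 / peak
        out.append(
            MetageneProfile(p.matrix * factor, p.settings, p.label, scale_factor=factor)
        )
    return out


def pas_tss_ratio(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    window_bp: int = 200,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene log2(PAS window sum / TSS window sum).

    Windows are window_bp long, ending at the PAS and starting at the
    TSS (strand-aware). Genes where either sum is 0 are excluded (the
    count is in ``df.attrs['n_excluded']``) unless a pseudocount is set.
    """
    rows = []
    n_excluded = 0
    for g in genes:
        bundle = derive_regions(g, window_bp=window_bp)
        s_pas = window_sum(track, bundle.pas_window) + pseudocount
        s_tss = window_sum(track, bundle.tss_window) + pseudocount
        if s_pas <= 0 or s_tss <= 0:
            n_excluded += 1
            continue
        rows.append((g.gene_id, s_pas, s_tss, float(np.log2(s_pas / s_tss))))
    df = pd.DataFrame(rows, columns=["gene_id", "s_pas", "s_tss", "log2_ratio"])
    df.attrs["n_excluded"] = n_excluded
    if n_excluded:
        logger.info("pas_tss_ratio: excluded %d genes with zero window sum", n_excluded)
    return df


@dataclass
class ActivityGroups:
    """Equal-size gene groups ranked by mean signal (1 = least active)."""

    n_groups: int
    assignment: dict[str, int]
    dropped: list[str] = field(default_factory=list)

    def members(self, rank: int) -> list[str]:
        return sorted(g for g, r in self.assignment.items() if r == rank)


def activity_groups(
    total_track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_extension_bp: int = 5000,
    n_groups: int = 5,
) -> ActivityGroups:
    """Rank genes by mean signal over gene body + 3' extension.

    Genes are sorted ascending by mean per-base signal (ties broken by
    gene_id, so assignment is deterministic); the n mod n_groups
    least-active genes are dropped so all groups are exactly equal.
    """
    if len(genes) < n_groups:
        raise ValueError(f"need >= {n_groups} genes, got {len(genes)}")
    scored = []
    for g in genes:
        region = derive_regions(g, body_extension_bp=body_extension_bp).body_plus_extension
        mean = window_sum(total_track, region) / region.length
        scored.append((mean, g.gene_id))
    scored.sort()
    n = len(scored)
    r = n % n_groups
    dropped = [gid for _, gid in scored[:r]]
    kept = scored[r:]
    size = len(kept) // n_groups
    assignment = {
        gid: (i // size) + 1 for i, (_, gid) in enumerate(kept)
    }
    return ActivityGroups(n_groups, assignment, dropped)


def group_profiles(
    mark_track: CoverageTrack,
    groups: ActivityGroups,
    genes: Sequence[GeneModel],
    settings: MetageneSettings = MetageneSettings(),
    body_extension_bp: int = 5000,
) -> dict[int, MetageneProfile]:
    """Metagene per activity group over gene body + 3' extension regions."""
    by_id = {g.gene_id: g for g in genes}
    out: dict[int, MetageneProfile] = {}
    for rank in range(1, groups.n_groups + 1):
        members = groups.members(rank)
        if not members:
            raise ValueError(f"activity group {rank} is empty")
        regions = [
            derive_regions(by_id[gid], body_extension_bp=body_extension_bp).body_plus_extension
            for gid in members
        ]
        out[rank] = metagene(mark_track, regions, settings, label=f"group{rank}")
    return out


def profile_to_frame(profile: MetageneProfile) -> pd.DataFrame:
    s = profile.settings
    kinds = (
        ["upstream"] * s.n_flank_bins
        + ["body"] * s.n_body_bins
        + ["downstream"] * s.n_flank_bins
    )
    return pd.DataFrame(
        {"bin": range(s.n_bins), "kind": kinds, "mean_signal": profile.profile}
    )


def plot_profiles(profiles: Sequence[MetageneProfile], path: str) -> None:
    """Simple line plot of average profiles (one line per track)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.profile, label=p.label or None)
    s = profiles[0].settings
    if s.n_flank_bins:
        for x in (s.n_flank_bins, s.n_flank_bins + s.n_body_bins):
            ax.axvline(x, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("bin (5' → 3')")
    ax.set_ylabel("mean signal")
    if any(p.label for p in profiles):
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
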