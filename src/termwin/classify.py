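"""Three-way classification of termination windows.

Relative to a preselected gene set, a consensus window is:

* ``gene_end`` — overlaps (>= 1 bp) the region from a gene's PAS to
  ``downstream_bp`` past it (same strand): termination after the
  annotated 3' end, where most protein-coding transcription terminates;
* ``premature`` — fully contained in a gene body (same strand), without
  touching any PAS-downstream region: intragenic terminal pausing,
  typically at intronic cryptic PASs;
* ``other`` — everything else (intergenic, or near genes excluded by the
  preselection).

gene_end takes priority over premature when both predicates hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .calling import TerminationWindowSet
from .intervals import GenomicInterval

CATEGORIES = ("gene_end", "premature", "other")


@dataclass(frozen=True)
class ClassParams:
    downstream_bp: int = 6000
    priority: tuple[str, str] = ("gene_end", "premature")

    def __post_init__(self) -> None:
        if self.downstream_bp <= 0:
            raise ValueError("downstream_bp must be > 0")
        if sorted(self.priority) != ["gene_end", "premature"]:
            raise ValueError("priority must order gene_end and premature")


@dataclass(frozen=True)
class ClassifiedWindow:
    interval: GenomicInterval
    category: str
    gene_id: Optional[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.gene_id is None) != (self.category == "other"):
            raise ValueError("gene_id present iff category != other")

    @property
    def length_bp(self) -> int:
        return self.interval.length


def _pas_downstream(gene: GeneModel, downstream_bp: int) -> GenomicInterval:
    if gene.strand == "+":
        return GenomicInterval(
            gene.contig, gene.pas, gene.pas + downstream_bp, gene.strand
        )
    return GenomicInterval(
        gene.contig, max(gene.pas - downstream_bp, 0), gene.pas, gene.strand
    )


def classify(
    windows: TerminationWindowSet | Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    params: ClassParams = ClassParams(),
) -> list[ClassifiedWindow]:
    """Assign exactly one category per window.

    Tie-break when several genes assign the same category: the gene whose
    PAS (gene_end) or body start (premature) is nearest the window
    midpoint, then lexicographically smallest gene_id.
    """
    if isinstance(windows, TerminationWindowSet):
        window_list = windows.windows
    else:
        window_list = list(windows)

    by_strand: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_strand.setdefault((g.contig, g.strand), []).append(g)

    out: list[ClassifiedWindow] = []
    for w in window_list:
        cands = by_strand.get((w.contig, w.strand), [])
        assigned: Optional[ClassifiedWindow] = None
        for category in params.priority:
            if category == "gene_end":
                hits = [
                    g
                    for g in cands
                    if _pas_downstream(g, params.downstream_bp).overlaps(w)
                ]
                if hits:
                    mid = w.midpoint()
                    best = min(hits, key=lambda g: (abs(g.pas - mid), g.gene_id))
                    assigned = ClassifiedWindow(w, "gene_end", best.gene_id)
                    break
            else:
                hits = [g for g in cands if g.interval.contains(w)]
                if hits:
                    mid = w.midpoint()
                    best = min(
                        hits, key=lambda g: (abs(g.interval.start - mid), g.gene_id)
                    )
                    assigned = ClassifiedWindow(w, "premature", best.gene_id)
                    break
        out.append(assigned or ClassifiedWindow(w, "other", None))
    return out


def window_stats(classified: Sequence[ClassifiedWindow]) -> pd.DataFrame:
    """Per-category count and length quartiles.

    Median uses the lower-median convention for even n; quartiles use the
    'lower' order statistic. Empty categories report NaN.
    """
    rows = []
    for category in CATEGORIES:
        lengths = np.sort(
            [w.length_bp for w in classified if w.category == category]
        )
        n = len(lengths)
        if n == 0:
            rows.append((category, 0, np.nan, np.nan, np.nan))
            continue
        median = float(lengths[(n - 1) // 2])
        q1 = float(np.percentile(lengths, 25, method="lower"))
        q3 = float(np.percentile(lengths, 75, method="lower"))
        rows.append((category, n, median, q1, q3))
    return pd.DataFrame(
        rows, columns=["category", "n", "median_length", "q1_length", "q3_length"]
    )


def classified_to_table(classified: Sequence[ClassifiedWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_id": [f"TW{i + 1:05d}" for i in range(len(classified))],
            "contig": [w.interval.contig for w in classified],
            "start": [w.interval.start for w in classified],
            "end": [w.interval.end for w in classified],
            "strand": [w.interval.strand for w in classified],
            "category": [w.category for w in classified],
            "gene_id": [w.gene_id or "" for w in classified],
            "length_bp": [w.length_bp for w in classified],
        }
    )


def classified_to_bed(classified: Sequence[ClassifiedWindow], path: str) -> None:
    """BED6 with category embedded in the name field."""
    with open(path, "w") as fh:
        for i, w in enumerate(classified):
            iv = w.interval
            name = f"TW{i + 1:05d}|{w.category}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
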