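"""Gene annotation: GTF parsing, gene preselection, strand-aware regions.

The preselection mirrors a common practice when quantifying signal around
gene 3' ends: keep protein-coding genes that (a) do not overlap another
annotated gene on the same strand and (b) have a 3' end isolated by at
least ``isolation_bp`` (default 6 kb) from the start of the next annotated
gene downstream on the same strand. This excludes artifacts from closely
spaced tandem genes, at the cost of discarding genes in dense clusters.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and PAS.

    ``tss``/``pas`` are positions (not intervals): on the + strand
    tss == interval.start and pas == interval.end; on the - strand the
    roles swap. ``pas`` is the annotated 3' end of the mature transcript;
    Pol II transcribes past it before terminating.
    """

    gene_id: str
    biotype: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def pas(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class SelectionParams:
    """Gene-preselection filters.

    isolation_bp: minimum distance (inclusive) from a gene's PAS to the
        strand-aware start of the nearest downstream gene on the same strand.
    overlap_any_biotype: the overlap filter considers every annotated gene
        regardless of biotype; set False to restrict to the biotype filter set.
    """

    biotype_filter: frozenset[str] = frozenset({"protein_coding"})
    isolation_bp: int = 6000
    overlap_any_biotype: bool = True

    def __post_init__(self) -> None:
        if self.isolation_bp < 0:
            raise ValueError("isolation_bp must be >= 0")


@dataclass(frozen=True)
class RegionBundle:
    """Strand-aware regions derived from one gene (all half-open)."""

    pas_downstream: GenomicInterval
    tss_window: GenomicInterval
    pas_window: GenomicInterval
    body_plus_extension: GenomicInterval


def load_annotation(gtf_source: str) -> list[GeneModel]:
    """Parse gene records from a GTF file (plain or gzip).

    Coordinates are converted from GTF 1-based inclusive to internal
    0-based half-open. Records without a usable strand are skipped (count
    logged as a warning); an unparseable record fails with its line number.
    """
    _validate_gtf_lines(gtf_source)
    db = gffutils.create_db(
        gtf_source,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    n_skipped = 0
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            n_skipped += 1
            continue
        biotype = _first_attr(feat, ("gene_type", "gene_biotype", "biotype"))
        gene_id = _first_attr(feat, ("gene_id",))
        if gene_id is None:
            n_skipped += 1
            continue
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes.append(GeneModel(gene_id, biotype or "", interval))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} gene records without strand or gene_id")
    return genes


def _validate_gtf_lines(path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"{path}: unparseable GTF record at line {lineno}")


def _first_attr(feat, keys: Sequence[str]) -> Optional[str]:
    for key in keys:
        if key in feat.attributes:
            vals = feat.attributes[key]
            if vals:
                return vals[0]
    return None


def select_genes(
    genes: Iterable[GeneModel], params: SelectionParams = SelectionParams()
) -> list[GeneModel]:
    """Apply the preselection filters; output sorted by (contig, start).

    A gene G is retained iff:
      (a) its biotype is in ``params.biotype_filter``;
      (b) its interval overlaps no other annotated gene on the same strand;
      (c) the nearest gene on the same strand whose strand-aware start lies
          downstream of G's PAS begins >= isolation_bp past the PAS
          (inclusive; absence of any downstream gene passes).
    """
    all_genes = list(genes)
    candidates = [g for g in all_genes if g.biotype in params.biotype_filter]
    if not candidates:
        return []
    overlap_pool = all_genes if params.overlap_any_biotype else candidates

    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in overlap_pool:
        by_key.setdefault((g.contig, g.strand), []).append(g)
    prepared = {}
    for key, gl in by_key.items():
        starts = np.array([g.interval.start for g in gl], dtype=np.int64)
        ends = np.array([g.interval.end for g in gl], dtype=np.int64)
        ids = np.array([g.gene_id for g in gl], dtype=object)
        # strand-aware "start" of each gene = its TSS
        tss = np.sort(np.array([g.tss for g in gl], dtype=np.int64))
        prepared[key] = (starts, ends, ids, tss)

    selected = []
    for g in candidates:
        starts, ends, ids, tss = prepared[(g.contig, g.strand)]
        # (b) any *other* same-strand gene overlapping?
        hit = (starts < g.interval.end) & (ends > g.interval.start) & (ids != g.gene_id)
        if hit.any():
            continue
        # (c) isolation: nearest same-strand TSS strictly downstream of PAS
        if g.strand == "+":
            # downstream genes have TSS >= pas (a gene abutting the PAS counts)
            j = int(np.searchsorted(tss, g.pas, side="left"))
            if j < len(tss) and tss[j] - g.pas < params.isolation_bp:
                continue
        else:
            j = int(np.searchsorted(tss, g.pas, side="right"))
            if j > 0 and g.pas - tss[j - 1] < params.isolation_bp:
                continue
        selected.append(g)
    selected.sort(key=lambda g: (g.contig, g.interval.start, g.gene_id))
    return selected


def derive_regions(
    gene: GeneModel,
    downstream_bp: int = 6000,
    window_bp: int = 200,
    body_extension_bp: int = 5000,
    contig_sizes: Optional[dict[str, int]] = None,
) -> RegionBundle:
    """Strand-aware analysis regions for one gene.

    pas_downstream: [pas, pas + downstream_bp) in transcription direction —
        the region where most protein-coding transcription terminates.
    tss_window / pas_window: fixed windows starting at the TSS / ending at
        the PAS (used for promoter-vs-terminator signal ratios).
    body_plus_extension: the gene body extended body_extension_bp past the PAS.

    Regions are clipped to [0, contig size] when sizes are supplied; a
    region running past a known contig end is clipped, past an unknown end
    emitted unclipped with a warning.
    """
    if min(downstream_bp, window_bp, body_extension_bp) <= 0:
        raise ValueError("region lengths must be positive")
    c, s = gene.contig, gene.strand
    if s == "+":
        raw = {
            "pas_downstream": (gene.pas, gene.pas + downstream_bp),
            "tss_window": (gene.tss, gene.tss + window_bp),
            "pas_window": (gene.pas - window_bp, gene.pas),
            "body_plus_extension": (gene.interval.start, gene.pas + body_extension_bp),
        }
    else:
        raw = {
            "pas_downstream": (gene.pas - downstream_bp, gene.pas),
            "tss_window": (gene.tss - window_bp, gene.tss),
            "pas_window": (gene.pas, gene.pas + window_bp),
            "body_plus_extension": (gene.pas - body_extension_bp, gene.interval.end),
        }
    size = contig_sizes.get(c) if contig_sizes else None
    out = {}
    for name, (a, b) in raw.items():
        a2 = max(a, 0)
        b2 = b
        if size is not None:
            b2 = min(b, size)
        elif contig_sizes is not None:
            warnings.warn(f"contig {c} absent from sizes; region {name} unclipped")
        out[name] = GenomicInterval(c, a2, b2, s)
    return RegionBundle(**out)


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["contig", "size"])
    return dict(zip(df["contig"], df["size"].astype(int)))


def genes_to_bed(genes: Sequence[GeneModel], path: str) -> None:
    """Write genes as BED6 (name=gene_id, score=0)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")


def genes_to_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "contig": [g.contig for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "pas": [g.pas for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )
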