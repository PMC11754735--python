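"""Synthetic strand-specific nascent-transcription coverage with planted
termination structure.

The generator emulates the statistical shape of T4ph-marked mNET-seq
signal: low pervasive background, elevated gene-body signal, a strong
enrichment block starting 0.5-2 kb downstream of each gene's PAS (the
planted gene-end termination window), optional intronic premature-
termination blocks, a small 5' TSS bump, and independent Poisson noise
per replicate. Five replicates in two sets (3 + 2) mirror a two-study
replicate design.

Rate units: scenario lambdas are expressed in *read-pileup* units — the
expected value of the 150-bp-extended signal the downstream caller
operates on (the scale on which broad-calling cutoffs are defined). The
raw single-nucleotide track is drawn at ``lambda / extension_length_bp``
per base, so that the pipeline's extension step reproduces the stated
depth. Body-level signal continues through the gene-end window region
(polymerase is still on the template while pausing) and drops to
background after it.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import GeneModel
from .classify import ClassifiedWindow
from .coverage import CoverageTrack, write_bedgraph
from .intervals import GenomicInterval


@dataclass
class SimScenario:
    """A stated synthetic world; defaults are scenario S1 minus the seed."""

    seed: int = 1
    n_contigs: int = 2
    contig_length_bp: int = 1_400_000
    n_genes: int = 200  # total, split evenly over contigs and strands
    gene_length_min: int = 3000
    gene_length_max: int = 10000
    intergenic_gap_bp: int = 12000  # >= PAS isolation by construction
    lambda_background: float = 0.01  # pileup units; see module docstring
    lambda_body: float = 0.2
    lambda_window: float = 2.0
    window_offset_min: int = 500  # gene-end window starts this far past PAS
    window_offset_max: int = 2000
    window_length_log_mean: float = float(np.log(2000.0))
    window_length_log_sd: float = 0.4
    premature_fraction: float = 0.3
    premature_length_log_mean: float = float(np.log(1500.0))
    premature_length_log_sd: float = 0.4
    replicate_sets: tuple[int, ...] = (3, 2)
    tss_peak_rate: float = 0.6
    tss_peak_width: int = 200
    extension_length_bp: int = 150
    assembly_tag: str = "sim"

    def __post_init__(self) -> None:
        for name in ("lambda_background", "lambda_body", "lambda_window",
                     "tss_peak_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.premature_fraction <= 1:
            raise ValueError("premature_fraction must be in [0, 1]")
        if len(self.replicate_sets) < 2 or any(r < 1 for r in self.replicate_sets):
            raise ValueError("need >= 2 replicate sets of >= 1 replicate")

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "replicate_sets" in d:
            d["replicate_sets"] = tuple(d["replicate_sets"])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth (all intervals genomic half-open)."""

    genes: list[GeneModel]
    gene_end_windows: list[tuple[str, GenomicInterval]]  # (gene_id, interval)
    premature_windows: list[tuple[str, GenomicInterval]]

    @property
    def all_windows(self) -> list[tuple[str, str, GenomicInterval]]:
        return [("gene_end", g, iv) for g, iv in self.gene_end_windows] + [
            ("premature", g, iv) for g, iv in self.premature_windows
        ]


@dataclass
class SimResult:
    scenario: SimScenario
    truth: SimTruth
    # strand -> list over sets -> list over replicates
    tracks: dict[str, list[list[CoverageTrack]]]
    # (contig, strand) -> raw per-base Poisson rate (single replicate)
    rates: dict[tuple[str, str], np.ndarray]


def _layout(scenario: SimScenario, rng: np.random.Generator) -> SimTruth:
    """Place genes and planted windows; selection filters hold by construction."""
    genes: list[GeneModel] = []
    gene_end: list[tuple[str, GenomicInterval]] = []
    premature: list[tuple[str, GenomicInterval]] = []
    per_cell = scenario.n_genes / (scenario.n_contigs * 2)
    quota = int(np.ceil(per_cell))
    placed_total = 0
    margin = 8000  # keep clear of contig start (room for metagene flanks)
    for ci in range(scenario.n_contigs):
        contig = f"chrS{ci + 1}"
        for strand in ("+", "-"):
            cursor = margin
            n_here = min(quota, scenario.n_genes - placed_total)
            for k in range(n_here):
                glen = int(
                    rng.integers(scenario.gene_length_min, scenario.gene_length_max + 1)
                )
                offset = int(
                    rng.integers(scenario.window_offset_min, scenario.window_offset_max + 1)
                )
                wlen = max(
                    200,
                    int(
                        round(
                            rng.lognormal(
                                scenario.window_length_log_mean,
                                scenario.window_length_log_sd,
                            )
                        )
                    ),
                )
                span = offset + wlen
                gap = max(scenario.intergenic_gap_bp, span + 1000)
                if strand == "+":
                    gstart = cursor
                    gend = gstart + glen
                    w = GenomicInterval(contig, gend + offset, gend + offset + wlen, strand)
                    cursor = gend + gap
                else:
                    gstart = cursor + gap
                    gend = gstart + glen
                    w = GenomicInterval(contig, gstart - offset - wlen, gstart - offset, strand)
                    cursor = gend
                if max(gend, w.end) > scenario.contig_length_bp - margin:
                    raise ValueError(
                        f"contig {contig} too short for requested gene count"
                    )
                gid = f"SIMG_{contig}_{strand}_{k + 1:04d}"
                gene = GeneModel(gid, "protein_coding", GenomicInterval(contig, gstart, gend, strand))
                genes.append(gene)
                gene_end.append((gid, w))
                placed_total += 1
                if rng.random() < scenario.premature_fraction:
                    piv = _place_premature(scenario, rng, gene)
                    if piv is not None:
                        premature.append((gid, piv))
    genes.sort(key=lambda g: (g.contig, g.interval.start))
    return SimTruth(genes, gene_end, premature)


def _place_premature(
    scenario: SimScenario, rng: np.random.Generator, gene: GeneModel
) -> Optional[GenomicInterval]:
    """Premature window fully inside the body, clear of TSS bump and PAS.

    The PAS margin (1 kb) keeps the weak-signal gap to the gene-end window
    larger than the caller's linking gap, so planted windows stay distinct.
    """
    tss_margin, pas_margin = 500 + scenario.tss_peak_width, 1000
    iv = gene.interval
    for _ in range(10):
        plen = max(
            200,
            int(
                round(
                    rng.lognormal(
                        scenario.premature_length_log_mean,
                        scenario.premature_length_log_sd,
                    )
                )
            ),
        )
        free = iv.length - tss_margin - pas_margin - plen
        if free < 0:
            continue
        off = int(rng.integers(0, free + 1))
        if gene.strand == "+":
            start = iv.start + tss_margin + off
        else:
            start = iv.start + pas_margin + off
        return GenomicInterval(iv.contig, start, start + plen, gene.strand)
    return None


def rate_arrays(
    scenario: SimScenario, truth: SimTruth
) -> dict[tuple[str, str], np.ndarray]:
    """Raw per-base Poisson rate for one replicate, per (contig, strand)."""
    L = scenario.extension_length_bp
    rates: dict[tuple[str, str], np.ndarray] = {}
    for ci in range(scenario.n_contigs):
        contig = f"chrS{ci + 1}"
        for strand in ("+", "-"):
            rates[(contig, strand)] = np.full(
                scenario.contig_length_bp, scenario.lambda_background / L
            )
    ge_by_gene = dict(truth.gene_end_windows)
    for gene in truth.genes:
        arr = rates[(gene.contig, gene.strand)]
        w = ge_by_gene[gene.gene_id]
        # body-level signal continues from TSS through the gene-end window
        if gene.strand == "+":
            body_lo, body_hi = gene.interval.start, w.end
            tss_lo = gene.tss
        else:
            body_lo, body_hi = w.start, gene.interval.end
            tss_lo = gene.tss - scenario.tss_peak_width
        arr[body_lo:body_hi] += scenario.lambda_body / L
        arr[max(tss_lo, 0) : tss_lo + scenario.tss_peak_width] += (
            scenario.tss_peak_rate / L
        )
        arr[w.start : w.end] += scenario.lambda_window / L
    for gid, piv in truth.premature_windows:
        arr = rates[(piv.contig, piv.strand)]
        arr[piv.start : piv.end] += scenario.lambda_window / L
    return rates


def simulate(scenario: SimScenario, out_dir: Optional[str] = None) -> SimResult:
    """Generate annotation, replicate tracks and planted truth.

    Fully reproducible from the scenario (which carries the seed): the
    layout and every (set, replicate, strand, contig) Poisson stream use
    fixed-offset substreams of the master seed, so adding replicates
    never perturbs existing ones.
    """
    layout_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([scenario.seed, 0]))
    )
    truth = _layout(scenario, layout_rng)
    rates = rate_arrays(scenario, truth)
    tracks: dict[str, list[list[CoverageTrack]]] = {"+": [], "-": []}
    for si, n_reps in enumerate(scenario.replicate_sets):
        for strand in ("+", "-"):
            tracks[strand].append([])
        for ri in range(n_reps):
            for strand_i, strand in enumerate(("+", "-")):
                dense: dict[str, np.ndarray] = {}
                for ci in range(scenario.n_contigs):
                    contig = f"chrS{ci + 1}"
                    rng = np.random.Generator(
                        np.random.PCG64(
                            np.random.SeedSequence(
                                [scenario.seed, 1 + si, ri, strand_i, ci]
                            )
                        )
                    )
                    dense[contig] = rng.poisson(rates[(contig, strand)]).astype(
                        np.float64
                    )
                tracks[strand][si].append(
                    CoverageTrack.from_dense(strand, dense, scenario.assembly_tag)
                )
    result = SimResult(scenario, truth, tracks, rates)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: SimResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    sc = result.scenario
    with open(os.path.join(out_dir, "annotation.gtf"), "w") as fh:
        for g in result.truth.genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(
                f"{iv.contig}\ttermwin_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
    strand_tag = {"+": "plus", "-": "minus"}
    for strand, sets in result.tracks.items():
        for si, reps in enumerate(sets):
            for ri, track in enumerate(reps):
                name = f"set{si + 1}_rep{ri + 1}.{strand_tag[strand]}.bedgraph"
                write_bedgraph(track, os.path.join(out_dir, name))
    with open(os.path.join(out_dir, "truth.bed"), "w") as fh:
        for cat, gid, iv in result.truth.all_windows:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{cat}|{gid}\t0\t{iv.strand}\n"
            )
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("category\tgene_id\tcontig\tstart\tend\tstrand\n")
        for cat, gid, iv in result.truth.all_windows:
            fh.write(f"{cat}\t{gid}\t{iv.contig}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
    with open(os.path.join(out_dir, "scenario.json"), "w") as fh:
        json.dump(asdict(sc), fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class RecoveryReport:
    sensitivity: float
    precision: float
    category_accuracy: float
    n_truth: int
    n_called: int
    n_recovered: int
    per_category_sensitivity: dict[str, float] = field(default_factory=dict)


def evaluate_recovery(
    called: Sequence[ClassifiedWindow],
    truth: SimTruth,
    min_jaccard: float = 0.5,
) -> RecoveryReport:
    """Match planted windows to called windows by interval Jaccard.

    A truth window is recovered if its best same-strand called window has
    Jaccard >= min_jaccard; category accuracy is computed over recovered
    (matched) pairs; precision is the fraction of called windows matching
    some truth window at the threshold.
    """
    truth_windows = truth.all_windows
    recovered = 0
    cat_ok = 0
    per_cat_n: dict[str, int] = {}
    per_cat_rec: dict[str, int] = {}
    matched_called: set[int] = set()
    for cat, _, tiv in truth_windows:
        per_cat_n[cat] = per_cat_n.get(cat, 0) + 1
        best_j, best_i = 0.0, -1
        for i, cw in enumerate(called):
            if cw.interval.strand != tiv.strand:
                continue
            j = tiv.jaccard(cw.interval)
            if j > best_j:
                best_j, best_i = j, i
        if best_j >= min_jaccard:
            recovered += 1
            per_cat_rec[cat] = per_cat_rec.get(cat, 0) + 1
            matched_called.add(best_i)
            if called[best_i].category == cat:
                cat_ok += 1
    # precision: called windows with a truth match at the threshold
    n_prec = 0
    for i, cw in enumerate(called):
        best = max(
            (
                tiv.jaccard(cw.interval)
                for _, _, tiv in truth_windows
                if tiv.strand == cw.interval.strand
            ),
            default=0.0,
        )
        if best >= min_jaccard:
            n_prec += 1
    n_truth = len(truth_windows)
    return RecoveryReport(
        sensitivity=recovered / n_truth if n_truth else float("nan"),
        precision=n_prec / len(called) if called else float("nan"),
        category_accuracy=cat_ok / recovered if recovered else float("nan"),
        n_truth=n_truth,
        n_called=len(called),
        n_recovered=recovered,
        per_category_sensitivity={
            c: per_cat_rec.get(c, 0) / n for c, n in per_cat_n.items()
        },
    )
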