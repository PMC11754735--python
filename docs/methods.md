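# Methods

## Problem and data model

Nascent-transcription protocols such as mNET-seq record the genomic
position of elongating RNA polymerase II at single-nucleotide resolution,
strand-specifically, via the 3′ end of the nascent RNA. A coverage track is
therefore a sparse, non-negative per-base count signal, one file per strand
per replicate. Termination of protein-coding transcription happens after
the polyadenylation site (PAS): Pol II continues downstream, pauses
terminally — marked by CTD threonine-4 phosphorylation — and releases.
`termwin` defines **termination windows** as consensus regions of broad
T4ph-style enrichment and classifies them relative to a curated gene set.

All coordinates are 0-based half-open. GTF input (1-based inclusive) is
converted on read; BED is written natively. Tracks are run-length encoded
per contig; absent positions are zero. Operations densify one contig at a
time, which bounds memory at one float per base of the largest contig.

## Gene preselection

To avoid attributing downstream-of-PAS signal to the wrong gene, only
genes with a clean 3′ neighborhood are analyzed. A gene is retained iff:

* its biotype is in the filter set (default `protein_coding`);
* its interval overlaps no *other* annotated gene (any biotype) on the
  same strand — the overlap filter deliberately considers all biotypes,
  since an overlapping lncRNA contaminates the signal as much as an
  overlapping coding gene (configurable via `overlap_any_biotype`);
* the nearest same-strand gene starting downstream of its PAS
  (strand-aware TSS-to-PAS distance) begins ≥ `isolation_bp` (default
  6000) past the PAS; the bound is inclusive, and a gene abutting the PAS
  (distance 0) violates it.

Gene-level records define TSS and PAS; per-transcript isoforms and
alternative-polyadenylation catalogs are out of scope.

## Signal preparation

* **Replicate averaging** is a per-base arithmetic mean over the union of
  covered regions, treating absence as 0 (the behavior of the usual
  multi-track averaging tools). Means are computed on a breakpoint sweep,
  so the result is exact and run-length minimal.
* **Signal extension** inflates each recorded base to a read-sized
  interval (default 150 bp), summing contributions. The anchor is the
  recorded position as the 5′ end in strand orientation ([p, p+150) on +,
  (p−150, p] on −); this matches the default of interval-resizing
  utilities, which treat the recorded nucleotide as the read start. A
  `center` anchor is available since the raw data do not pin the choice
  down. Extension conserves total signal (×150) except where intervals
  are clipped at position 0.

## Two-tier broad calling

On the averaged, extended track of each study:

1. *strong* regions: maximal runs of value > `cutoff_peak`, internal gaps
   ≤ `max_gap_within` closed;
2. *weak* (link) regions: maximal runs of value > `cutoff_link`, gaps
   ≤ `max_gap_link` closed;
3. strong regions inside the same link region are joined; the emitted
   region spans from the first to the last joined strong region, which
   includes the weak signal connecting them but not weak flanks beyond the
   outermost strong regions;
4. regions shorter than `min_length` are dropped.

Defaults (2.0 / 1.0 / 200 bp / 30 bp / 800 bp) are the documented defaults
of the classic bedGraph broad-peak caller. Comparisons are strictly
greater-than. The implementation operates on run-length segments; a
per-base brute-force oracle in the test suite guards exact region-for-
region equivalence on hundreds of randomized tracks.

## Consensus and merging

A region is kept iff it overlaps (≥ 1 bp, same strand) at least one region
called from the other study; the retained pool is merged into maximal
disjoint windows. Book-ended intervals (end == start) are coalesced —
consistent with half-open adjacency in standard interval-reduction
semantics (`merge_adjacent` exposed in the API). With more than two
studies, a region must overlap a region from ≥ 1 other study; all-way
overlap is intentionally not required. Provenance (contributing source
regions) is recorded per window.

## Classification

Categories are assigned in priority order — `gene_end` (≥ 1 bp overlap with
[PAS, PAS+6 kb) of a preselected gene, same strand), then `premature`
(full containment in a gene body), then `other` — so a window satisfying
both predicates is `gene_end`; the order is configurable. Ties between
genes assigning the same category break to the gene whose PAS (gene_end)
or body start (premature) is nearest the window midpoint, then to the
lexicographically smallest gene_id, making classification invariant to
input order. Length summaries use the lower-median convention for even
counts and `lower`-interpolated quartiles; at realistic window counts the
convention is numerically irrelevant.

## Profile metrics

* **Metagene (scale-regions)**: each region's body is divided into
  `n_body_bins` equal (possibly fractional) bins — bin value = mean
  per-base signal, computed from the exact integral of the step function —
  with fixed-width flank bins (`flank_bp`/`bin_bp`) on both sides; minus-
  strand rows are reversed so all rows read 5′→3′. Flank bins reaching
  before position 0 treat the missing bases as zero, keeping geometry
  aligned. Default geometry: 100 body bins, 5 kb flanks, 10 bp bins.
* **Unit-max scaling**: per track, factor = 1 / max(average profile); the
  matrix is rescaled by the factor. Binning is linear in the signal, so
  multiplying the matrix equals recomputing it from a scaled track; the
  factor is returned for reuse.
* **PAS/TSS ratio**: per gene, log₂ of the signal sum in the 200-bp window
  ending at the PAS over the sum in the 200-bp window starting at the TSS.
  Genes with a zero sum in either window are excluded and counted rather
  than pseudocounted (a pseudocount option exists, default off).
* **Activity groups**: genes ranked ascending by mean per-base signal over
  gene body + 5 kb; the *n* mod *k* least-active genes are dropped so the
  *k* (default 5) groups are exactly equal — the only remainder scheme
  consistent with published full-scale group sizes (five groups of 2077
  from 10 387 genes). Ties order by gene_id, so assignment is
  deterministic.

## Synthetic data generator

The generator emulates the statistical shape of termination-marked
nascent-transcription coverage on a small genome (default: 2 × 1.4 Mb
contigs, 200 genes split over contigs and strands, gene lengths uniform
3–10 kb, same-strand gaps ≥ 12 kb so the preselection filters hold by
construction):

* low pervasive background; elevated gene-body signal from TSS onward;
* one planted **gene-end window** per gene, starting uniformly 500–2000 bp
  downstream of the PAS (where real T4ph enrichment peaks), length
  LogNormal(log 2000, 0.4); body-level signal continues through the window
  (the polymerase is still on the template while pausing) and falls to
  background after it;
* optional **premature windows** (30 % of genes), LogNormal(log 1500, 0.4),
  placed fully inside the body, ≥ 700 bp from the TSS and ≥ 1 kb from the
  PAS — the PAS margin keeps the weak-signal gap to the gene-end window
  above the caller's 800-bp linking gap so planted windows stay distinct;
* a small 5′ TSS bump (0.6 pileup units over 200 bp), below the weak
  cutoff, as in real T4ph data where TSS signal is detectable but far
  below termination-window enrichment;
* independent Poisson counts per replicate; two replicate sets of 3 and 2,
  mirroring a two-study design.

**Rate units.** Scenario lambdas (background 0.01, body 0.2, window 2.0)
are expressed in *read-pileup* units: the expected value of the 150-bp-
extended signal that the broad caller actually thresholds, which is the
scale on which its cutoffs are defined (pileups of read-length intervals).
The raw single-nucleotide track is drawn at λ/150 per base, so the
pipeline's extension step reproduces the stated depth: window regions sit
at ≈ 2.21 (above the 2.0 strong cutoff), gene bodies at ≈ 0.21 (below the
1.0 weak cutoff), background at ≈ 0.01. Stating rates on the raw-track
scale instead would make every gene body exceed the strong cutoff after
extension (0.21 × 150 ≈ 31), fusing bodies and windows into single calls
and making planted-window recovery impossible by construction — an
internally inconsistent world rather than a harder one.

Seeding: a master seed; the layout and every (set, replicate, strand,
contig) Poisson stream use fixed-offset `SeedSequence` substreams, so runs
are byte-reproducible and adding replicates never perturbs existing ones.

**What a green synthetic test establishes.** The generator produces
rectangular enrichment blocks with sharp edges, no splicing structure, no
antisense TSS transcription, no mappability or GC artifacts, and replicate
noise that is exactly Poisson and independent. Recovery ≥ 90 % at Jaccard
≥ 0.5 on this world validates the pipeline's interval logic, thresholds and
strand handling end-to-end — it does not certify performance on real
libraries, where fragmentation of windows (a known artifact of threshold
calling on noisy signal) and non-Poisson overdispersion appear.

Recovery scoring: a planted window is recovered if some same-strand called
window reaches interval Jaccard ≥ 0.5; category accuracy is computed over
matched pairs; precision is the fraction of called windows matching any
planted window.

## Numerical choices

* Values are doubles; bedGraph is written with 6 significant digits
  (configurable) and read/write round-trips are bit-comparable at that
  precision.
* Near-zero residues (< 1e−12) from breakpoint arithmetic are clamped to
  zero so run-length encodings stay minimal.
* Metagene bin means are exact integrals of the step function (no per-base
  discretization error); the test suite checks them against a per-base
  oracle at 1e−12.
* Degenerate inputs: empty gene sets and empty tracks yield empty outputs,
  not errors; a single replicate set is an error (no consensus is
  possible); unit-max scaling of an all-zero profile is an error naming
  the track.

## Known limitations

* bigWig I/O is not implemented (no bigWig library in the supported
  environment); convert to bedGraph first, as the underlying method itself
  does before calling.
* Windows are not refined to single-nucleotide resolution, and no
  de-fragmentation heuristic is applied beyond the caller's linking gap —
  fragmented windows are reported as called.
* The full-scale published counts (13 488 windows; 3566 gene-end / 1376
  premature / 8546 other; medians 2900 and 1559 bp) require the original
  GEO coverage tracks and GENCODE v40 on hg38; this repository's tests are
  desk-scale and do not assert them.
* Chromosome-name dialects ("chr1" vs "1") must agree between tracks and
  annotation; no automatic normalization is applied.
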