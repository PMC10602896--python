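# Methods

## Scope and model

splicemark analyses the relationship between a chromatin mark's coverage
signal and gene structure: where peaks sit (promoter/exon/intron/
intergenic), how mean signal differs between exons and introns, and
whether splice-junction signal distinguishes alternatively spliced exons
from their constitutive neighbours. It deliberately consumes the outputs
of the standard upstream tools — CPM-normalized coverage (bamCoverage-style),
MACS2 narrowPeak, rMATS junction-count event tables, DESeq2-style DE
results — and reimplements only the downstream computations, natively.
Peak calling, read alignment, inclusion-level estimation and dispersion
modelling are out of scope by design.

## Coordinates and formats

All internal coordinates are 0-based half-open. GTF (1-based closed) is
converted on ingest and back on export; BED, narrowPeak and the rMATS
`*Start_0base`/`*End` columns are taken verbatim. Tracks are stored as
dense per-chromosome float arrays, which is exact and fast at the
genome sizes this package targets (tens of megabases); uncovered bases
read as 0, matching the common coverage-tool convention. bedGraph is the
canonical text interchange; bigWig is read through pyBigWig when
installed, behind the same loader.

## Feature derivation

Introns are the gaps between consecutive exons of a transcript. The
promoter is TSS ± 2 kb by default (configurable); no community standard
exists and ±2 kb is the common convention for promoter–peak assignment.
The canonical transcript is the one with the greatest total exonic
length, ties broken lexicographically by transcript id — deterministic
and annotation-agnostic. Genomic-location classification uses the
precedence promoter > exon > intron > intergenic with ≥1 bp overlap; the
same ≥1 bp rule is used for promoter–peak assignment, CGI partitioning
and peak turnover, with a configurable minimum-overlap fraction left to
future need.

For the exon–intron signal comparison, features are filtered per
transcript: the 5′-most exon is removed (it carries TSS-proximal signal,
which would otherwise masquerade as exonic enrichment), then exons
< 200 bp and introns < 500 bp are discarded. The filter provenance
(thresholds, first-exon flag, per-transcript application) is recorded on
the resulting feature set.

## Junction-window comparison

For each selected event the alternative exon and its two adjacent
("constitutive") exons contribute one window per boundary:
[s − flank, s + flank) and [e − flank, e + flank) with flank = 100 bp.
Windows are symmetric about the splice junction so exonic and intronic
context are represented equally. Windows are clamped at chromosome
bounds (logged). Per event, window means are averaged within
(class, side); Welch's unequal-variance *t*-test is used everywhere a
group comparison is reported — it is the robust default when only
"Student's *t*-test" is specified — and Benjamini–Hochberg adjustment is
applied across marks when several tracks are compared at once. Profiles
are binned means across windows, flipped so bin 0 is always 5′.
"Normalization" before the junction comparison means library-level CPM
(v × 10⁶ / total mapped reads); no per-event rescaling is applied.

Skipped-exon (SE) events are the validated primary class. RI windows are
built on the retained intron (the gap between the flanking exons), and
A5SS/A3SS on the long exon with its flanking exon as the comparison
class; these are provided but not exercised by the recovery analyses.
Significance is FDR ≤ 0.05, boundary inclusive, as is every other
threshold in the package (mean TPM ≥ 1; |log2FC| ≥ 1 with
adjusted p ≤ 0.05).

## Exon–intron density

Per-class density is the unweighted mean over features of each feature's
per-base mean signal. Equal per-feature weighting is deliberate: introns
average several kilobases against ~200–450 bp exons, and base-pooled
averaging would let a handful of long introns dominate the intron
estimate. The exon:intron ratio is scale-equivariant (CPM scaling cancels
in the ratio).

## Synthetic data and what it does (not) show

The generator lays out non-overlapping multi-exon genes (default 3–6
exons of 120–400 bp, introns 500–1500 bp, both strands, ≥4.5 kb
intergenic gaps) so that exon lengths straddle the 200 bp filter and all
introns pass the 500 bp filter. Coverage is
`background × (ρ on exonic bases, 1 elsewhere) × (δ over each planted
alternative exon ± junction flank)` plus a promoter bump and Gaussian
noise clipped at 0. Two planting choices matter:

* δ is applied over the alternative exon *extended by the junction
  flank*, i.e. over exactly the region the junction windows measure, so
  the alternative/constitutive window-mean ratio is an unbiased
  estimator of δ. Noise sd 0.1 against background 2.0 makes clipping
  negligible.
* No exon appears in two planted events of the same type, so one event's
  depleted alternative exon can never sit inside another event's
  constitutive windows.

Event tables realise significance deterministically (significant events
draw FDR in [0, 0.049] with one event pinned at exactly 0.05; the rest
draw in (0.05, 1]), and the DE/TPM tables likewise realise each gene's
intended class, including genes at exactly the threshold values, so the
threshold rules can be checked for exact recovery including boundaries.
Expression coupling: promoter-occupied genes are down-regulated with a
configurable probability (default 0.8) and an effect of −2 log2 units.
All randomness flows from one seed; identical seeds give byte-identical
files.

The generator emulates the *structure* the pipeline consumes, not
sequencing reality: no read-level noise model, no mappability or GC
structure, no overlapping genes or alternative TSSs, no correlated
replicate structure in the tables. Passing recovery tests therefore
demonstrates correctness of the computations under the stated planted
model, not robustness to the biases of real libraries.

## Validation conditions and numerical choices

The recovery analyses run at sizes chosen to keep estimator noise well
inside the stated tolerances on a single CPU: exon:intron recovery on a
300-gene genome (ρ = 3.0, noise sd 0.1, tolerance ±5%); junction
depletion on 200 significant SE events (δ = 0.5, tolerance ±0.05,
detection at p < 0.01); null calibration of the junction test over 1000
replicates on a fixed 60-gene genome with 60 events, redrawing only the
track noise (empirical type-I error expected in [0.03, 0.07] at
α = 0.05). Oracle comparisons (metaprofiles vs direct per-position
averaging, Pearson vs the product-moment formula) use tolerances 1e−9
and 1e−12 respectively; set-overlap machinery is compared exactly
against exhaustive brute force.

Degenerate inputs: zero-length intervals, non-positive CPM totals,
double normalization, single-event comparisons, empty feature classes
and zero-variance correlation columns are all hard errors; off-chromosome
metaprofile windows are clamped and zero-padded (keeping row counts equal
to anchor counts) and bodies shorter than the bin count fall back to
nearest-base assignment, both logged rather than raised.

## Known limitations

* Dense track arrays are memory-proportional to genome size; a real
  mammalian genome at base resolution would need a run-length or chunked
  backend behind the same `CoverageTrack` contract.
* The constitutive class is defined locally (adjacent exons of the same
  event), not transcriptome-wide; exons constitutive in one isoform but
  alternative in another are not reconciled.
* MXE events use the first alternative exon only; A5SS/A3SS junction
  windows are untested against planted truth.
* The feature filters are applied per transcript, so an exon shared by
  two transcripts can contribute twice to the density estimate; a merged
  exon-union mode is a possible extension.
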