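# splicemark

Integrative analysis of chromatin-mark coverage around gene structure and
alternative splicing. The package targets the downstream half of a
CUT&Tag + RNA-seq study design: given CPM-normalized coverage tracks,
MACS2 peak calls, rMATS-style alternative-splicing tables, and a
differential-expression results table, it asks where a histone mark sits
relative to promoters, exons and introns, and whether its signal at splice
junctions distinguishes alternatively spliced exons from their
constitutive neighbours.

## What it computes

**Metaprofiles.** Reference-point profiles (mean signal in fixed bins over
±flank around TSS/TES/CGI anchors, strand-flipped so bin 0 is 5′) and
scaled gene-body profiles, computed natively from bedGraph/bigWig tracks
with uncovered bases read as 0.

**Junction-window comparison.** For significant skipped-exon events
(FDR ≤ 0.05), each exon boundary gets a window of ±100 bp; the exons
adjacent to the alternative exon serve as the within-gene constitutive
comparison class. Per event, the mean CPM signal in each window is
computed and Welch *t*-tests compare (i) the 5′ vs 3′ side within each
exon class and (ii) alternative vs constitutive windows. The
alternative/constitutive mean ratio is the effect-size summary.

**Exon–intron signal attribution.** Exon and intron features are filtered
before comparison: the 5′-most (first) exon of each transcript is removed
to exclude TSS-proximal signal, exons shorter than 200 bp and introns
shorter than 500 bp are discarded. Per-class density is the mean of
per-feature per-base means (each feature weighted equally, so
multi-kilobase introns cannot dominate), and the exon:intron ratio is the
headline statistic.

**Peak integration.** narrowPeak ingest, peak classification by a
promoter > exon > intron > intergenic precedence, promoter–peak gene
assignment (≥1 bp overlap), CGI vs non-CGI promoter-peak partitioning,
two-condition shared/gained/lost peak turnover, and Venn-style gene-set
overlap reports.

**Expression thresholds.** Expressed genes at mean TPM ≥ 1; differentially
expressed genes at |log2FC| ≥ 1 with adjusted p ≤ 0.05 (both boundaries
inclusive); and the Livak 2^−ΔΔCt relative-expression computation for
qPCR Ct tables.

**Mark correlation.** Region × track signal matrices, product-moment
correlation between marks, and average-linkage grouping on 1 − r.

Because real sequencing depth is out of reach for desk-scale validation,
the package ships a first-class synthetic-data generator
(`splicemark.simulate`) that emits the complete artifact set — GTF,
chrom.sizes, CGI BED, per-mark bedGraph and narrowPeak, rMATS-style
tables, DE/TPM/qPCR tables — with a truth manifest recording every planted
parameter (exon:intron ratio ρ, junction depletion δ, promoter–peak gene
couplings, significant-event identities), so every stage is validated by
recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on a generated
dataset (120 genes, planted ρ = 3.0, δ = 0.5, noise sd 0.1):

```
python analysis/01_simulate.py
python analysis/02_metaprofiles.py
python analysis/03_peak_annotation.py
python analysis/04_expression.py
python analysis/05_splicing.py
```

The final driver prints, per mark:

```
SE: 22 significant events (planted 22)
H4R3me2a: junction alt/const ratio 0.493 (p=8.90e-20); exon:intron ratio 2.921
H4R3me2s: junction alt/const ratio 0.493 (p=9.09e-20); exon:intron ratio 2.921
H3K4me3:  junction alt/const ratio 0.925 (p=3.29e-01); exon:intron ratio 0.981
mark correlation (average-linkage order): H3K4me3 -> H4R3me2a -> H4R3me2s
```

Read: the FDR ≤ 0.05 rule recovers exactly the planted significant events;
the two methylarginine-like marks carry the planted ~3× exonic enrichment
and the planted 2× depletion at alternative-exon junctions
(ratio ≈ 0.5, strongly significant), while the active-mark control shows
neither (ratio ≈ 1 within noise, p ≫ 0.05); and the correlation step
groups the two co-planted marks together (r ≈ 1.0) away from the control
(r ≈ 0.4). Tables land under `results/`.

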