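"""Synthetic dataset generator with a machine-readable truth manifest.

Emits a fully self-contained toy dataset — genome annotation (GTF +
chrom.sizes), CpG islands (BED), per-mark coverage tracks (bedGraph), peak
calls (narrowPeak), rMATS-style AS tables, DE/TPM/qPCR tables — with every
planted parameter recorded so each pipeline stage can be validated by
recovery.

Planted structure
-----------------
* exon:intron signal ratio ``rho``: exonic bases carry ``rho x background``,
  intronic and intergenic bases ``1 x background``.
* junction depletion ``delta``: the signal over each planted alternative
  exon, extended by the junction flank on both sides, is multiplied by
  ``delta`` — so the alternative/constitutive junction-window mean ratio
  recovers ``delta`` directly.
* promoter occupancy: a subset of genes gets a promoter signal bump and a
  matching narrowPeak call; a subset of promoters carries a CGI.
* expression coupling: genes gaining the planted repressive mark are
  down-regulated with a configurable probability.

All randomness flows through one ``numpy`` Generator per seed; the same
seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, define_promoters, write_gtf
from .coverage import CoverageTrack, write_bedgraph
from .intervals import GenomicInterval
from .peaks import Peak, write_narrowpeak
from .splicing import EVENT_TYPES, JUNCTION_FLANK


class SimulationError(ValueError):
    pass


@dataclass
class TruthManifest:
    """Planted parameters of one synthetic dataset."""

    seed: int
    n_genes: int
    rho: float = 1.0  # exon:intron signal ratio
    delta: float = 1.0  # alternative-exon junction multiplier
    junction_flank: int = JUNCTION_FLANK
    promoter_peak_genes: list[str] = field(default_factory=list)
    cgi_promoter_genes: list[str] = field(default_factory=list)
    significant_event_ids: dict[str, list[str]] = field(default_factory=dict)
    alt_exon_regions: list[list] = field(default_factory=list)  # [chrom, s, e]
    deg_truth: dict[str, list[str]] = field(default_factory=dict)
    expressed_genes: list[str] = field(default_factory=list)
    repressive_gain_genes: list[str] = field(default_factory=list)
    coupling: dict = field(default_factory=dict)
    qpcr_truth: dict[str, float] = field(default_factory=dict)
    peak_truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ToyGenome:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    cgi: list[GenomicInterval]
    manifest: TruthManifest

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def promoters(
        self, upstream: int = 2000, downstream: int = 2000
    ) -> dict[str, GenomicInterval]:
        return define_promoters(
            self.genes, upstream, downstream, chrom_sizes=self.chrom_sizes
        )


def generate_toy_genome(
    seed: int,
    n_chroms: int = 2,
    n_genes: int = 100,
    exons_per_gene_range: tuple[int, int] = (3, 6),
    exon_len_range: tuple[int, int] = (120, 400),
    intron_len_range: tuple[int, int] = (500, 1500),
    intergenic_gap: int = 4500,
    promoter_peak_fraction: float = 0.3,
    cgi_promoter_fraction: float = 0.5,
    max_chrom_size: int = 50_000_000,
) -> ToyGenome:
    """Lay out non-overlapping multi-exon genes on both strands.

    Exon lengths straddle the 200 bp filter boundary and introns are always
    >= 500 bp, so the annotation filters are genuinely exercised. A stated
    fraction of promoters gets a planted peak and/or a CGI.
    """
    if n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    if exons_per_gene_range[0] < 1 or exons_per_gene_range[0] > exons_per_gene_range[1]:
        raise SimulationError("invalid exons_per_gene_range")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gidx = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = intergenic_gap
        for _ in range(per_chrom):
            if gidx >= n_genes:
                break
            n_exons = int(rng.integers(exons_per_gene_range[0],
                                       exons_per_gene_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exon_lens = rng.integers(
                exon_len_range[0], exon_len_range[1] + 1, size=n_exons
            )
            intron_lens = (
                rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                             size=n_exons - 1)
                if n_exons > 1
                else np.array([], dtype=int)
            )
            exons = []
            pos = cursor
            for i, el in enumerate(exon_lens):
                exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
                pos += int(el)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            gene_id = f"gene{gidx:04d}"
            tx = TranscriptModel(f"{gene_id}.t1", exons, strand)
            genes.append(GeneModel(gene_id, strand, [tx]))
            cursor = pos + intergenic_gap
            gidx += 1
            if cursor > max_chrom_size:
                raise SimulationError(
                    f"genome too small for requested genes on {chrom}"
                )
        chrom_sizes[chrom] = cursor + intergenic_gap
    if gidx < n_genes:
        raise SimulationError("could not place all requested genes")

    gene_ids = [g.gene_id for g in genes]
    n_peak = int(round(promoter_peak_fraction * n_genes))
    promoter_peak_genes = sorted(
        rng.choice(gene_ids, size=n_peak, replace=False).tolist()
    )
    n_cgi = int(round(cgi_promoter_fraction * n_genes))
    cgi_promoter_genes = sorted(
        rng.choice(gene_ids, size=n_cgi, replace=False).tolist()
    )
    cgi = []
    for g in genes:
        if g.gene_id in cgi_promoter_genes:
            tss = g.canonical_tss
            lo = max(0, tss - 200)
            hi = min(chrom_sizes[g.chrom], tss + 200)
            cgi.append(GenomicInterval(g.chrom, lo, hi, "."))
    cgi.sort(key=lambda iv: (iv.chrom, iv.start))

    manifest = TruthManifest(
        seed=seed,
        n_genes=n_genes,
        promoter_peak_genes=promoter_peak_genes,
        cgi_promoter_genes=cgi_promoter_genes,
    )
    return ToyGenome(genes, chrom_sizes, cgi, manifest)


def generate_as_table(
    genome: ToyGenome,
    rng: np.random.Generator,
    n_events_per_type: Mapping[str, int] | int = 50,
    frac_significant: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """rMATS JC-style tables for the five event types with planted truth.

    Significant events get FDR <= 0.05 (one per type pinned exactly at the
    0.05 boundary when possible), the rest FDR > 0.05. IncLevelDifference
    is signed: > 0 means higher inclusion in condition 1 (perturbed).
    Updates ``genome.manifest`` with the significant event ids and the
    alternative-exon regions of significant SE events.
    """
    if isinstance(n_events_per_type, int):
        n_events_per_type = {t: n_events_per_type for t in EVENT_TYPES}
    # candidate exon windows per type: (gene, central exon index)
    triples = [
        (g, i)
        for g in genome.genes
        for i in range(1, len(g.canonical.exons) - 1)
    ]
    quads = [
        (g, i)
        for g in genome.genes
        for i in range(1, len(g.canonical.exons) - 2)
    ]
    pairs = [
        (g, i)
        for g in genome.genes
        for i in range(len(g.canonical.exons) - 1)
    ]
    capacity = {
        "SE": triples, "A5SS": pairs, "A3SS": pairs, "MXE": quads, "RI": pairs
    }
    # exon indices an event occupies, relative to its slot index i
    span = {"SE": (-1, 1), "A5SS": (0, 1), "A3SS": (0, 1),
            "MXE": (-1, 2), "RI": (0, 1)}
    tables: dict[str, pd.DataFrame] = {}
    genome.manifest.significant_event_ids = {}
    for etype in EVENT_TYPES:
        # no exon reused within a type: keeps each event's constitutive
        # windows clear of another event's planted alternative exon
        used: set[tuple[str, int]] = set()
        n = n_events_per_type.get(etype, 0)
        slots = capacity[etype]
        if n > len(slots):
            raise SimulationError(
                f"{etype}: requested {n} events but only {len(slots)} "
                "exon windows available"
            )
        lo_off, hi_off = span[etype]
        chosen: list[tuple[GeneModel, int]] = []
        for si in rng.permutation(len(slots)):
            gene, i = slots[si]
            keys = [(gene.gene_id, i + o) for o in range(lo_off, hi_off + 1)]
            if any(k in used for k in keys):
                continue  # no exon shared between two planted events
            used.update(keys)
            chosen.append((gene, i))
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise SimulationError(
                f"{etype}: requested {n} events but only {len(chosen)} "
                "non-overlapping exon windows available"
            )
        n_sig = int(round(frac_significant * n))
        rows = []
        sig_ids = []
        for k, (gene, i) in enumerate(chosen):
            exons = gene.canonical.exons
            significant = k < n_sig
            if significant:
                # pin the first significant event at the inclusive boundary
                fdr = 0.05 if k == 0 else float(rng.uniform(0.0, 0.049))
                ild = float(rng.uniform(0.1, 0.9)) * (
                    1 if rng.random() < 0.5 else -1
                )
                sig_ids.append(f"{etype}_{k}")
            else:
                fdr = 0.051 if k == n_sig else float(rng.uniform(0.051, 1.0))
                ild = float(rng.uniform(-0.05, 0.05))
            row = {
                "ID": k,
                "GeneID": gene.gene_id,
                "geneSymbol": gene.gene_id,
                "chr": gene.chrom,
                "strand": gene.strand,
                "PValue": round(fdr * float(rng.uniform(0.2, 1.0)), 6),
                "FDR": round(fdr, 6),
                "IncLevelDifference": round(ild, 4),
            }
            if etype == "SE":
                row.update(
                    exonStart_0base=exons[i].start, exonEnd=exons[i].end,
                    upstreamES=exons[i - 1].start, upstreamEE=exons[i - 1].end,
                    downstreamES=exons[i + 1].start, downstreamEE=exons[i + 1].end,
                )
                if significant:
                    genome.manifest.alt_exon_regions.append(
                        [gene.chrom, exons[i].start, exons[i].end]
                    )
            elif etype == "MXE":
                row.update(
                    **{
                        "1stExonStart_0base": exons[i].start,
                        "1stExonEnd": exons[i].end,
                        "2ndExonStart_0base": exons[i + 1].start,
                        "2ndExonEnd": exons[i + 1].end,
                    },
                    upstreamES=exons[i - 1].start, upstreamEE=exons[i - 1].end,
                    downstreamES=exons[i + 2].start, downstreamEE=exons[i + 2].end,
                )
            elif etype in {"A5SS", "A3SS"}:
                # long exon and its flanking exon in genomic order
                long_e, flank_e = exons[i], exons[i + 1]
                if etype == "A3SS":
                    long_e, flank_e = exons[i + 1], exons[i]
                row.update(
                    longExonStart_0base=long_e.start, longExonEnd=long_e.end,
                    shortES=long_e.start, shortEE=long_e.end - 30,
                    flankingES=flank_e.start, flankingEE=flank_e.end,
                )
            elif etype == "RI":
                row.update(
                    riExonStart_0base=exons[i].start, riExonEnd=exons[i + 1].end,
                    upstreamES=exons[i].start, upstreamEE=exons[i].end,
                    downstreamES=exons[i + 1].start, downstreamEE=exons[i + 1].end,
                )
            rows.append(row)
        tables[etype] = pd.DataFrame(rows)
        genome.manifest.significant_event_ids[etype] = sig_ids
    return tables


def generate_coverage_track(
    genome: ToyGenome,
    rng: np.random.Generator,
    background: float = 2.0,
    promoter_amplitude: float = 0.0,
    rho: float = 1.0,
    delta: float = 1.0,
    noise_sd: float = 0.1,
    name: str = "mark",
) -> CoverageTrack:
    """Plant a coverage track from the genome's truth structure.

    Signal = background x (rho on exonic bases, 1 elsewhere), x delta over
    each planted alternative exon extended by the junction flank, plus a
    promoter bump of ``promoter_amplitude`` (+/-300 bp around the TSS of
    each planted promoter-peak gene), plus Gaussian noise clipped at 0.
    """
    if background < 0 or promoter_amplitude < 0 or rho < 0 or delta < 0:
        raise SimulationError("amplitudes must be non-negative")
    arrays = {
        chrom: np.full(size, background, dtype=float)
        for chrom, size in genome.chrom_sizes.items()
    }
    for gene in genome.genes:
        for exon in gene.canonical.exons:
            arrays[exon.chrom][exon.start : exon.end] = background * rho
    flank = genome.manifest.junction_flank
    for chrom, s, e in genome.manifest.alt_exon_regions:
        lo = max(0, s - flank)
        hi = min(len(arrays[chrom]), e + flank)
        arrays[chrom][lo:hi] *= delta
    if promoter_amplitude > 0:
        for gene in genome.genes:
            if gene.gene_id in genome.manifest.promoter_peak_genes:
                tss = gene.canonical_tss
                lo = max(0, tss - 300)
                hi = min(len(arrays[gene.chrom]), tss + 300)
                arrays[gene.chrom][lo:hi] += promoter_amplitude
    if noise_sd > 0:
        for chrom in sorted(arrays):
            arrays[chrom] += rng.normal(0.0, noise_sd, size=arrays[chrom].size)
            np.clip(arrays[chrom], 0.0, None, out=arrays[chrom])
    genome.manifest.rho = rho
    genome.manifest.delta = delta
    track = CoverageTrack(arrays, normalized=True, name=name)
    return track


def generate_peak_calls(
    genome: ToyGenome,
    rng: np.random.Generator,
    mark: str = "mark",
    gene_subset: Sequence[str] | None = None,
    n_background: int = 20,
    peak_halfwidth: int = 200,
) -> list[Peak]:
    """narrowPeak calls at planted promoter-peak genes plus background.

    ``gene_subset`` restricts promoter peaks to those genes (used to plant
    shared/gained/lost truth between two conditions); default is every
    planted promoter-peak gene.
    """
    subset = (
        list(gene_subset)
        if gene_subset is not None
        else genome.manifest.promoter_peak_genes
    )
    peaks: list[Peak] = []
    for gene_id in subset:
        gene = genome.gene(gene_id)
        tss = gene.canonical_tss
        lo = max(0, tss - peak_halfwidth)
        hi = min(genome.chrom_sizes[gene.chrom], tss + peak_halfwidth)
        peaks.append(
            Peak(
                interval=GenomicInterval(gene.chrom, lo, hi, "."),
                name=f"{mark}_{gene_id}",
                score=float(rng.integers(100, 1000)),
                signal_value=float(np.round(rng.uniform(2, 20), 3)),
                neg_log10_p=float(np.round(rng.uniform(3, 12), 3)),
                neg_log10_q=float(np.round(rng.uniform(2, 10), 3)),
                summit_offset=(hi - lo) // 2,
            )
        )
    # background peaks in gene-free space (deep intergenic midpoints)
    chroms = sorted(genome.chrom_sizes)
    occupied = sorted(
        (g.chrom, g.canonical.start - 2500, g.canonical.end + 2500)
        for g in genome.genes
    )
    for b in range(n_background):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = genome.chrom_sizes[chrom]
        for _ in range(50):
            pos = int(rng.integers(peak_halfwidth, size - peak_halfwidth))
            if not any(
                c == chrom and s <= pos < e for c, s, e in occupied
            ):
                break
        peaks.append(
            Peak(
                interval=GenomicInterval(
                    chrom, pos - peak_halfwidth, pos + peak_halfwidth, "."
                ),
                name=f"{mark}_bg{b}",
                score=float(rng.integers(50, 300)),
                signal_value=float(np.round(rng.uniform(1, 5), 3)),
                neg_log10_p=float(np.round(rng.uniform(3, 6), 3)),
                neg_log10_q=float(np.round(rng.uniform(2, 4), 3)),
                summit_offset=peak_halfwidth,
            )
        )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def generate_differential_peak_calls(
    genome: ToyGenome,
    rng: np.random.Generator,
    mark: str = "mark",
    frac_shared: float = 0.5,
) -> tuple[list[Peak], list[Peak]]:
    """Two-condition peak sets with planted shared/lost/gained truth.

    Both conditions share ``frac_shared`` of the planted promoter-peak
    genes; the rest are split between condition-A-only ("lost" after
    perturbation) and condition-B-only ("gained"). Counts are recorded in
    the manifest under ``peak_truth``.
    """
    pool = list(genome.manifest.promoter_peak_genes)
    rng.shuffle(pool)
    n_shared = int(round(frac_shared * len(pool)))
    shared = pool[:n_shared]
    rest = pool[n_shared:]
    a_only = rest[: len(rest) // 2]
    b_only = rest[len(rest) // 2 :]
    peaks_a = generate_peak_calls(
        genome, rng, mark=f"{mark}_A", gene_subset=sorted(shared + a_only),
        n_background=0,
    )
    peaks_b = generate_peak_calls(
        genome, rng, mark=f"{mark}_B", gene_subset=sorted(shared + b_only),
        n_background=0,
    )
    genome.manifest.peak_truth = {
        "shared": len(shared),
        "lost": len(a_only),
        "gained": len(b_only),
    }
    return peaks_a, peaks_b


def generate_expression_tables(
    genome: ToyGenome,
    rng: np.random.Generator,
    p_down_given_repressive_gain: float = 0.8,
    effect_size_log2fc: float = 2.0,
    n_replicates: int = 3,
    frac_expressed: float = 0.8,
    frac_up: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """DE, TPM and qPCR tables coupled to the planted promoter occupancy.

    Genes gaining the repressive planted mark (the promoter-peak genes) are
    down-regulated with probability ``p_down_given_repressive_gain``. The
    emitted numbers deterministically realise each gene's intended class,
    including boundary rows (log2FC exactly 1.0 with padj exactly 0.05;
    mean TPM exactly 1.0 and exactly 0.99), and the realised truth lists
    are recorded in the manifest.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    gene_ids = [g.gene_id for g in genome.genes]
    repressive = list(genome.manifest.promoter_peak_genes)
    down_truth, up_truth = [], []
    rows = []
    others = [g for g in gene_ids if g not in repressive]
    n_up = int(round(frac_up * len(gene_ids)))
    up_pool = set(
        rng.choice(others, size=min(n_up, len(others)), replace=False).tolist()
    )
    for gene_id in gene_ids:
        if gene_id in repressive and rng.random() < p_down_given_repressive_gain:
            l2fc = -effect_size_log2fc + float(rng.normal(0, 0.2))
            l2fc = min(l2fc, -1.0)  # keep the planted class unambiguous
            padj = float(rng.uniform(1e-6, 0.04))
            down_truth.append(gene_id)
        elif gene_id in up_pool:
            l2fc = effect_size_log2fc + float(rng.normal(0, 0.2))
            l2fc = max(l2fc, 1.0)
            padj = float(rng.uniform(1e-6, 0.04))
            up_truth.append(gene_id)
        else:
            l2fc = float(np.clip(rng.normal(0, 0.3), -0.9, 0.9))
            padj = float(rng.uniform(0.051, 1.0))
        rows.append({"gene_id": gene_id, "log2fc": round(l2fc, 4),
                     "padj": round(padj, 6)})
    # boundary rows: exactly at and just inside/outside the DEG cutoffs
    if others:
        b0 = sorted(set(others) - up_pool)[:2]
        for gene_id, (l2fc, padj, is_deg) in zip(
            b0, [(1.0, 0.05, True), (0.9, 0.001, False)]
        ):
            for r in rows:
                if r["gene_id"] == gene_id:
                    r["log2fc"], r["padj"] = l2fc, padj
            if is_deg:
                up_truth.append(gene_id)
            elif gene_id in up_truth:
                up_truth.remove(gene_id)
    de = pd.DataFrame(rows)

    # TPM table: planted expressed/not-expressed with exact boundary genes
    n_expr = int(round(frac_expressed * len(gene_ids)))
    expressed = set(
        rng.choice(gene_ids, size=n_expr, replace=False).tolist()
    )
    tpm_rows = []
    boundary_hi, boundary_lo = None, None
    for gene_id in gene_ids:
        flat = False
        if gene_id in expressed:
            mean_tpm = float(np.round(rng.uniform(1.5, 100.0), 3))
            if boundary_hi is None:
                mean_tpm, boundary_hi, flat = 1.0, gene_id, True
        else:
            mean_tpm = float(np.round(rng.uniform(0.0, 0.95), 3))
            if boundary_lo is None:
                mean_tpm, boundary_lo, flat = 0.99, gene_id, True
        devs = np.round(rng.normal(0, 0.05 * mean_tpm, size=2 * n_replicates), 6)
        devs -= devs.mean()  # keep the mean exact
        vals = np.maximum(mean_tpm + devs, 0)
        # boundary genes stay flat so per-replicate rounding cannot move
        # their mean off the planted threshold value
        if flat or vals.mean() != mean_tpm:
            vals = np.full(2 * n_replicates, mean_tpm)
        row = {"gene_id": gene_id}
        for j in range(n_replicates):
            row[f"tpm_wt_{j + 1}"] = round(float(vals[j]), 6)
        for j in range(n_replicates):
            row[f"tpm_ko_{j + 1}"] = round(float(vals[n_replicates + j]), 6)
        tpm_rows.append(row)
    tpm = pd.DataFrame(tpm_rows)
    # recompute the truth from the rounded emitted values
    samp = [c for c in tpm.columns if c.startswith("tpm_")]
    expressed_truth = sorted(
        tpm.loc[tpm[samp].mean(axis=1) >= 1.0, "gene_id"]
    )

    # qPCR: a few down-truth targets with planted fold changes
    targets = sorted(down_truth)[:4] or gene_ids[:2]
    qpcr_rows = []
    qpcr_truth = {}
    for gene_id in targets:
        fold = float(np.round(rng.uniform(0.2, 0.6), 3))  # repressed
        control_dct = float(np.round(rng.uniform(2.0, 6.0), 3))
        treat_dct = control_dct - float(np.log2(fold))
        qpcr_truth[gene_id] = fold
        for cond, dct in (("control", control_dct), ("treatment", treat_dct)):
            for rep in range(1, n_replicates + 1):
                ref_ct = float(np.round(rng.uniform(16.0, 20.0), 3))
                qpcr_rows.append(
                    {
                        "sample_id": f"{gene_id}_{cond}_{rep}",
                        "gene_id": gene_id,
                        "condition": cond,
                        "replicate": rep,
                        "target_ct": round(ref_ct + dct, 4),
                        "reference_ct": round(ref_ct, 4),
                    }
                )
    qpcr = pd.DataFrame(qpcr_rows)

    genome.manifest.deg_truth = {
        "up": sorted(up_truth), "down": sorted(down_truth)
    }
    genome.manifest.expressed_genes = expressed_truth
    genome.manifest.repressive_gain_genes = sorted(down_truth)
    genome.manifest.coupling = {
        "p_down_given_repressive_gain": p_down_given_repressive_gain,
        "effect_size_log2fc": effect_size_log2fc,
        "n_replicates": n_replicates,
    }
    genome.manifest.qpcr_truth = qpcr_truth
    return {"de": de, "tpm": tpm, "qpcr": qpcr}


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcgi_{i}\t0\t{iv.strand}\n"
            )


def simulate_dataset(
    seed: int,
    out_dir: str | Path,
    n_genes: int = 100,
    rho: float = 3.0,
    delta: float = 0.5,
    noise_sd: float = 0.1,
    n_events_per_type: Mapping[str, int] | int | None = None,
    frac_significant: float = 0.3,
    marks: Sequence[str] = ("H4R3me2a", "H4R3me2s", "H3K4me3"),
) -> ToyGenome:
    """Generate and write the full artifact set for one seed.

    Emits GTF, chrom.sizes, CGI BED, per-mark bedGraph + narrowPeak,
    rMATS-style AS tables, DE/TPM/qPCR TSVs and ``manifest.json`` under
    ``out_dir``. Identical seeds yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_toy_genome(seed, n_genes=n_genes)
    rng = np.random.default_rng(seed + 1)
    if n_events_per_type is None:
        # scale with genome size; non-overlapping exon windows per type cap
        # the capacity at roughly one SE triple per gene
        n_events_per_type = {
            "SE": max(2, int(0.6 * n_genes)),
            "A5SS": max(2, int(0.25 * n_genes)),
            "A3SS": max(2, int(0.25 * n_genes)),
            "MXE": max(2, int(0.15 * n_genes)),
            "RI": max(2, int(0.25 * n_genes)),
        }
    tables = generate_as_table(
        genome, rng, n_events_per_type=n_events_per_type,
        frac_significant=frac_significant,
    )
    for etype, df in tables.items():
        df.to_csv(out / f"{etype}.MATS.JC.txt", sep="\t", index=False)

    for mi, mark in enumerate(marks):
        mark_rng = np.random.default_rng(seed + 100 + mi)
        # the active mark carries promoter bumps but no exon/junction planting
        active = mark.startswith("H3K")
        track = generate_coverage_track(
            genome, mark_rng,
            background=2.0,
            promoter_amplitude=8.0 if active else 3.0,
            rho=1.0 if active else rho,
            delta=1.0 if active else delta,
            noise_sd=noise_sd,
            name=mark,
        )
        write_bedgraph(track, out / f"{mark}.bedgraph")
        peaks = generate_peak_calls(genome, mark_rng, mark=mark)
        write_narrowpeak(peaks, out / f"{mark}.narrowPeak")
    genome.manifest.rho = rho
    genome.manifest.delta = delta

    expr_rng = np.random.default_rng(seed + 500)
    tabs = generate_expression_tables(genome, expr_rng)
    tabs["de"].to_csv(out / "de_results.tsv", sep="\t", index=False)
    tabs["tpm"].to_csv(out / "tpm.tsv", sep="\t", index=False)
    tabs["qpcr"].to_csv(out / "qpcr.tsv", sep="\t", index=False)

    write_gtf(genome.genes, out / "annotation.gtf")
    write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    write_bed(genome.cgi, out / "cgi.bed")
    genome.manifest.to_json(out / "manifest.json")
    return genome
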