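"""Gene annotation ingest and feature derivation.

Parses GTF gene models, derives introns and promoter windows, applies the
splicing-analysis feature filters (first-exon removal, minimum exon/intron
lengths) and classifies genomic locations against a promoter > exon >
intron > intergenic precedence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalIndex

# Default thresholds for the splicing-analysis feature filters.
MIN_EXON_LEN = 200
MIN_INTRON_LEN = 500
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 2000


class AnnotationError(ValueError):
    """Raised on malformed annotation input."""


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval]
    strand: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """5'-most coordinate: start on + strand, end on - strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def first_exon(self) -> GenomicInterval:
        """The 5'-most exon (strand-aware)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def total_exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    transcripts: list[TranscriptModel]
    canonical_transcript_id: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or strands != {self.strand}:
            raise AnnotationError(
                f"{self.gene_id}: transcripts disagree on chrom/strand"
            )
        if not self.canonical_transcript_id:
            self.canonical_transcript_id = _canonical_longest(self.transcripts)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def canonical(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.canonical_transcript_id:
                return t
        raise AnnotationError(
            f"{self.gene_id}: canonical transcript "
            f"{self.canonical_transcript_id!r} not found"
        )

    @property
    def canonical_tss(self) -> int:
        return self.canonical.tss

    @property
    def canonical_tes(self) -> int:
        return self.canonical.tes


@dataclass
class FeatureSet:
    """Exon/intron features surviving the splicing-analysis filters."""

    exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    provenance: dict = field(default_factory=dict)


def _canonical_longest(transcripts: Sequence[TranscriptModel]) -> str:
    """Longest total exonic length; ties broken lexicographically."""
    return min(
        transcripts, key=lambda t: (-t.total_exonic_length(), t.transcript_id)
    ).transcript_id


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gene_annotation(
    path: str | Path, canonical_rule: str = "longest"
) -> list[GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects.

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    Only ``exon`` features are consumed; transcripts are grouped by
    ``transcript_id`` and genes by ``gene_id``. One canonical transcript is
    flagged per gene: ``canonical_rule='longest'`` picks the transcript with
    the greatest total exonic length (ties by transcript_id).

    Raises
    ------
    AnnotationError
        naming the 1-based line number for lines lacking ``transcript_id``
        or with end < start.
    """
    if canonical_rule != "longest":
        raise ValueError(f"unknown canonical_rule {canonical_rule!r}")
    exons_by_tx: dict[tuple[str, str], list[GenomicInterval]] = {}
    tx_strand: dict[tuple[str, str], str] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise AnnotationError(f"line {lineno}: end {end1} < start {start1}")
            attrd = _parse_attributes(attrs)
            if "gene_id" not in attrd:
                raise AnnotationError(f"line {lineno}: missing gene_id attribute")
            if "transcript_id" not in attrd:
                raise AnnotationError(
                    f"line {lineno}: missing transcript_id attribute"
                )
            gene_id, tx_id = attrd["gene_id"], attrd["transcript_id"]
            key = (gene_id, tx_id)
            # GTF 1-based closed -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons_by_tx.setdefault(key, []).append(iv)
            tx_strand[key] = strand
            if gene_id not in gene_order:
                gene_order.append(gene_id)

    genes: list[GeneModel] = []
    for gene_id in gene_order:
        txs = [
            TranscriptModel(tx_id, exons, tx_strand[(gid, tx_id)])
            for (gid, tx_id), exons in exons_by_tx.items()
            if gid == gene_id
        ]
        txs.sort(key=lambda t: t.transcript_id)
        genes.append(GeneModel(gene_id, txs[0].strand, txs))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GTF (exon features only); round-trip safe."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{exon.chrom}\tsplicemark\texon\t{exon.start + 1}\t"
                        f"{exon.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Introns are the gaps between consecutive exons (genomic order)."""
    introns = []
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        if b.start < a.end:
            raise AnnotationError(
                f"{transcript.transcript_id}: overlapping exons"
            )
        if b.start > a.end:
            introns.append(
                GenomicInterval(a.chrom, a.end, b.start, transcript.strand)
            )
    return introns


def define_promoters(
    genes: Iterable[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """Promoter window per gene around the canonical TSS.

    For + strand genes the window is ``[TSS-upstream, TSS+downstream)``; for
    - strand genes it is mirrored. Windows are clamped to ``[0, chrom_len)``
    when ``chrom_sizes`` is given.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window has zero width")
    promoters: dict[str, GenomicInterval] = {}
    for gene in genes:
        tss = gene.canonical_tss
        if gene.strand == "-":
            lo, hi = tss - downstream, tss + upstream
        else:
            lo, hi = tss - upstream, tss + downstream
        lo = max(0, lo)
        if chrom_sizes is not None:
            if gene.chrom not in chrom_sizes:
                raise AnnotationError(
                    f"{gene.gene_id}: chromosome {gene.chrom!r} not in chrom_sizes"
                )
            hi = min(hi, chrom_sizes[gene.chrom])
        if hi <= lo:
            continue  # promoter entirely off-chromosome
        promoters[gene.gene_id] = GenomicInterval(gene.chrom, lo, hi, gene.strand)
    return promoters


def filter_splicing_features(
    transcripts: Iterable[TranscriptModel],
    min_exon_len: int = MIN_EXON_LEN,
    min_intron_len: int = MIN_INTRON_LEN,
    drop_first_exon: bool = True,
) -> FeatureSet:
    """Build the exon/intron sets used for signal-density comparison.

    The 5'-most exon of each transcript is removed when ``drop_first_exon``
    (excluding TSS-proximal signal), then exons shorter than
    ``min_exon_len`` and introns shorter than ``min_intron_len`` are
    discarded. Defaults follow the analysis convention of exon >= 200 bp
    and intron >= 500 bp. Filtering is applied per transcript.
    """
    if min_exon_len <= 0 or min_intron_len <= 0:
        raise ValueError("minimum lengths must be positive")
    exons: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    for tx in transcripts:
        kept = list(tx.exons)
        if drop_first_exon:
            first = tx.first_exon()
            kept = [e for e in kept if e != first]
        exons.extend(e for e in kept if len(e) >= min_exon_len)
        introns.extend(
            i for i in derive_introns(tx) if len(i) >= min_intron_len
        )
    if not exons and not introns:
        raise AnnotationError(
            "no features survive the filters "
            f"(min_exon_len={min_exon_len}, min_intron_len={min_intron_len})"
        )
    return FeatureSet(
        exons=exons,
        introns=introns,
        provenance={
            "min_exon_len": min_exon_len,
            "min_intron_len": min_intron_len,
            "drop_first_exon": drop_first_exon,
            "per_transcript": True,
        },
    )


def classify_genomic_location(
    query: GenomicInterval,
    promoters: IntervalIndex,
    exons: IntervalIndex,
    introns: IntervalIndex,
) -> str:
    """Assign promoter > exon > intron > intergenic by >=1-base overlap."""
    if promoters.any_overlap(query):
        return "promoter"
    if exons.any_overlap(query):
        return "exon"
    if introns.any_overlap(query):
        return "intron"
    return "intergenic"


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals (first 3-6 columns; strand honoured if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise AnnotationError(f"{path}: BED needs >= 3 columns")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] >= 6 and row[5] in {"+", "-"} else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))
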