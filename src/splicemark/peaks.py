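"""Peak-call integration: narrowPeak ingest, promoter assignment, CGI
partitioning, condition turnover and gene-set overlap reports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, IntervalIndex


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """A MACS2 narrowPeak record (BED6+4)."""

    interval: GenomicInterval
    name: str
    score: float
    signal_value: float
    neg_log10_p: float
    neg_log10_q: float
    summit_offset: int  # bp from start; -1 if absent

    def __post_init__(self) -> None:
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise PeakError(
                f"{self.name}: summit offset {self.summit_offset} outside peak"
            )

    @property
    def summit(self) -> int | None:
        if self.summit_offset == -1:
            return None
        return self.interval.start + self.summit_offset


def parse_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse a 10-column MACS2 narrowPeak file (0-based half-open)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise PeakError(
                    f"{path} line {lineno}: narrowPeak needs 10 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand, sv, p, q, summit = fields
            peaks.append(
                Peak(
                    interval=GenomicInterval(
                        chrom, int(start), int(end),
                        strand if strand in {"+", "-"} else ".",
                    ),
                    name=name,
                    score=float(score),
                    signal_value=float(sv),
                    neg_log10_p=float(p),
                    neg_log10_q=float(q),
                    summit_offset=int(summit),
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            strand = iv.strand if iv.strand in {"+", "-"} else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name}\t{pk.score:g}\t"
                f"{strand}\t{pk.signal_value:g}\t{pk.neg_log10_p:g}\t"
                f"{pk.neg_log10_q:g}\t{pk.summit_offset}\n"
            )


def promoter_peak_genes(
    peaks: Sequence[Peak], promoters: Mapping[str, GenomicInterval]
) -> tuple[set[str], dict[str, list[Peak]]]:
    """Genes whose promoter is overlapped (>= 1 base) by at least one peak.

    A peak spanning two promoters counts for both genes. Returns the gene
    set and the per-gene peak lists.
    """
    per_gene: dict[str, list[Peak]] = {}
    for gene_id, promoter in promoters.items():
        hits = [pk for pk in peaks if pk.interval.overlaps(promoter)]
        if hits:
            per_gene[gene_id] = hits
    return set(per_gene), per_gene


def partition_cgi_promoter_peaks(
    promoter_peaks: Sequence[Peak], cgi: Sequence[GenomicInterval]
) -> dict[str, list[Peak]]:
    """Split promoter peaks into CGI-overlapping vs non-CGI classes.

    The partition is exhaustive and disjoint: every input peak lands in
    exactly one class by the >=1-base overlap rule.
    """
    index = IntervalIndex.build(cgi)
    out: dict[str, list[Peak]] = {"cgi": [], "non_cgi": []}
    for pk in promoter_peaks:
        key = "cgi" if index.any_overlap(pk.interval) else "non_cgi"
        out[key].append(pk)
    return out


def differential_peak_sets(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> dict[str, list[Peak]]:
    """Classify peaks as shared vs condition-exclusive by >=1-base overlap.

    ``shared_a``/``shared_b`` are the overlapping peaks of each input (each
    peak counted once even when it overlaps several on the other side);
    ``lost`` are peaks only in A, ``gained`` peaks only in B.
    """
    index_b = IntervalIndex.build(pk.interval for pk in peaks_b)
    index_a = IntervalIndex.build(pk.interval for pk in peaks_a)
    shared_a, lost = [], []
    for pk in peaks_a:
        (shared_a if index_b.any_overlap(pk.interval) else lost).append(pk)
    shared_b, gained = [], []
    for pk in peaks_b:
        (shared_b if index_a.any_overlap(pk.interval) else gained).append(pk)
    return {
        "shared_a": shared_a,
        "shared_b": shared_b,
        "lost": lost,
        "gained": gained,
    }


@dataclass
class OverlapReport:
    """Venn-style report over 2-3 named gene sets."""

    labels: list[str]
    set_sizes: dict[str, int]
    region_counts: dict[frozenset, int]  # exclusive Venn regions
    intersections: dict[frozenset, int]  # all pairwise/higher-order |∩|
    memberships: dict[frozenset, list[str]]  # exclusive region members

    def region(self, *labels: str) -> int:
        """Exclusive Venn-region cardinality for exactly these labels."""
        return self.region_counts.get(frozenset(labels), 0)

    def intersection(self, *labels: str) -> int:
        """|∩| of the named sets (non-exclusive)."""
        return self.intersections[frozenset(labels)]


def overlap_gene_sets(named_sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """All Venn-region cardinalities and memberships for 2-3 gene sets.

    Duplicate identifiers within a set are collapsed with a warning.
    Membership lists are sorted for deterministic output.
    """
    if not (2 <= len(named_sets) <= 3):
        raise PeakError("overlap_gene_sets expects 2 or 3 named sets")
    sets: dict[str, set[str]] = {}
    for label, members in named_sets.items():
        members = list(members)
        uniq = set(members)
        if len(uniq) < len(members):
            warnings.warn(
                f"set {label!r}: {len(members) - len(uniq)} duplicate "
                "identifiers collapsed",
                stacklevel=2,
            )
        sets[label] = uniq
    labels = list(sets)
    universe = set().union(*sets.values())
    region_counts: dict[frozenset, int] = {}
    memberships: dict[frozenset, list[str]] = {}
    for gene in universe:
        key = frozenset(l for l in labels if gene in sets[l])
        region_counts[key] = region_counts.get(key, 0) + 1
        memberships.setdefault(key, []).append(gene)
    for key in memberships:
        memberships[key].sort()
    intersections: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set.intersection(*(sets[l] for l in combo))
            intersections[frozenset(combo)] = len(inter)
    return OverlapReport(
        labels=labels,
        set_sizes={l: len(sets[l]) for l in labels},
        region_counts=region_counts,
        intersections=intersections,
        memberships=memberships,
    )


def peak_location_fractions(
    peaks: Sequence[Peak],
    promoters: IntervalIndex,
    exons: IntervalIndex,
    introns: IntervalIndex,
) -> dict[str, float]:
    """Fraction of peaks per genomic class (promoter>exon>intron>intergenic).

    Fractions sum to 1 over classified peaks.
    """
    from .annotation import classify_genomic_location

    counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    for pk in peaks:
        counts[classify_genomic_location(pk.interval, promoters, exons, introns)] += 1
    total = len(peaks)
    if total == 0:
        raise PeakError("no peaks to classify")
    return {k: v / total for k, v in counts.items()}
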