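"""Alternative-splicing event tables and junction-window signal comparison.

Consumes rMATS-style junction-count tables (five event types: SE, A5SS,
A3SS, MXE, RI), selects significant events by FDR, builds +/-100 bp windows
around exon boundaries, and compares chromatin signal between alternative
and constitutive exons and between exons and introns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import FeatureSet
from .coverage import CoverageTrack, region_mean_signal
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")
SIGNIFICANT_FDR = 0.05
JUNCTION_FLANK = 100

# rMATS JC column names per event type: (alt exon cols, upstream, downstream)
_COLUMNS: dict[str, dict[str, tuple[str, str] | None]] = {
    "SE": {
        "alt": ("exonStart_0base", "exonEnd"),
        "up": ("upstreamES", "upstreamEE"),
        "down": ("downstreamES", "downstreamEE"),
    },
    "MXE": {
        "alt": ("1stExonStart_0base", "1stExonEnd"),
        "up": ("upstreamES", "upstreamEE"),
        "down": ("downstreamES", "downstreamEE"),
    },
    "A5SS": {
        "alt": ("longExonStart_0base", "longExonEnd"),
        "up": None,
        "down": ("flankingES", "flankingEE"),
    },
    "A3SS": {
        "alt": ("longExonStart_0base", "longExonEnd"),
        "up": ("flankingES", "flankingEE"),
        "down": None,
    },
    # RI: the alternative feature is the retained intron, i.e. the gap
    # between the flanking exons.
    "RI": {
        "alt": None,
        "up": ("upstreamES", "upstreamEE"),
        "down": ("downstreamES", "downstreamEE"),
    },
}


class SplicingError(ValueError):
    """Raised on malformed AS tables or contract violations."""


@dataclass
class ASEvent:
    """One rMATS-style alternative-splicing event.

    ``inc_level_difference`` follows the rMATS sign convention: > 0 means
    higher inclusion in condition 1 (the perturbed sample), < 0 higher
    inclusion in condition 2 (the control).
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    alt_exon: GenomicInterval
    upstream_exon: GenomicInterval | None
    downstream_exon: GenomicInterval | None
    inc_level_difference: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise SplicingError(f"unknown event type {self.event_type!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise SplicingError(
                f"{self.event_id}: FDR {self.fdr} outside [0, 1]"
            )
        if not (-1.0 <= self.inc_level_difference <= 1.0):
            raise SplicingError(
                f"{self.event_id}: IncLevelDifference outside [-1, 1]"
            )
        if self.event_type == "SE":
            up, down = self.upstream_exon, self.downstream_exon
            assert up is not None and down is not None
            if not (up.end <= self.alt_exon.start and self.alt_exon.end <= down.start):
                raise SplicingError(
                    f"{self.event_id}: exons violate genomic order"
                )

    @property
    def constitutive_exons(self) -> list[GenomicInterval]:
        """The adjacent flanking exons (the within-gene comparison class)."""
        return [e for e in (self.upstream_exon, self.downstream_exon) if e]

    @property
    def significant(self) -> bool:
        return self.fdr <= SIGNIFICANT_FDR

    @property
    def inclusion_bias(self) -> str:
        """Which condition includes the alternative feature more."""
        if self.inc_level_difference > 0:
            return "condition1"
        if self.inc_level_difference < 0:
            return "condition2"
        return "none"


def parse_as_events(path: str | Path, event_type: str) -> list[ASEvent]:
    """Parse an rMATS JC-style TSV into :class:`ASEvent` records.

    Coordinates are taken verbatim as 0-based half-open (the rMATS
    ``*Start_0base`` / ``*End`` convention). Missing required columns raise
    :class:`SplicingError` naming the column.
    """
    return events_from_frame(pd.read_csv(path, sep="\t"), event_type, source=str(path))


def events_from_frame(
    df: pd.DataFrame, event_type: str, source: str = "<frame>"
) -> list[ASEvent]:
    """Build :class:`ASEvent` records from an in-memory rMATS-style table."""
    if event_type not in EVENT_TYPES:
        raise SplicingError(f"unknown event type {event_type!r}")
    path = source
    spec = _COLUMNS[event_type]
    required = ["GeneID", "chr", "strand", "IncLevelDifference", "PValue", "FDR"]
    for part in ("alt", "up", "down"):
        cols = spec[part]
        if cols:
            required.extend(cols)
    for col in required:
        if col not in df.columns:
            raise SplicingError(f"{path}: missing required column {col!r}")

    events: list[ASEvent] = []
    for i, row in df.iterrows():
        chrom, strand = str(row["chr"]), str(row["strand"])

        def _iv(cols: tuple[str, str] | None) -> GenomicInterval | None:
            if cols is None:
                return None
            return GenomicInterval(chrom, int(row[cols[0]]), int(row[cols[1]]), strand)

        up, down = _iv(spec["up"]), _iv(spec["down"])
        if event_type == "RI":
            assert up is not None and down is not None
            alt = GenomicInterval(chrom, up.end, down.start, strand)
        else:
            alt = _iv(spec["alt"])
            assert alt is not None
        event_id = str(row["ID"]) if "ID" in df.columns else str(i)
        events.append(
            ASEvent(
                event_id=f"{event_type}_{event_id}",
                gene_id=str(row["GeneID"]),
                event_type=event_type,
                chrom=chrom,
                strand=strand,
                alt_exon=alt,
                upstream_exon=up,
                downstream_exon=down,
                inc_level_difference=float(row["IncLevelDifference"]),
                pvalue=float(row["PValue"]),
                fdr=float(row["FDR"]),
            )
        )
    return events


def classify_significant_events(
    events: Iterable[ASEvent], max_fdr: float = SIGNIFICANT_FDR
) -> tuple[dict[str, int], list[ASEvent]]:
    """Split events at FDR <= ``max_fdr`` (boundary inclusive).

    Returns per-type significant counts (all five types reported, zeros
    included) and the significant subset.
    """
    counts = {t: 0 for t in EVENT_TYPES}
    significant = []
    for ev in events:
        if ev.fdr <= max_fdr:
            counts[ev.event_type] += 1
            significant.append(ev)
    return counts, significant


@dataclass(frozen=True)
class JunctionWindow:
    event_id: str
    exon_class: str  # "alternative" | "constitutive"
    side: str  # "5p" | "3p", strand-aware
    window: GenomicInterval


@dataclass
class JunctionWindowSet:
    """Splice-junction windows (+/- flank bp around each exon boundary)."""

    windows: list[JunctionWindow]
    flank: int
    n_events: int

    def by_group(self) -> dict[tuple[str, str], list[JunctionWindow]]:
        groups: dict[tuple[str, str], list[JunctionWindow]] = {}
        for w in self.windows:
            groups.setdefault((w.exon_class, w.side), []).append(w)
        return groups


def _boundary_windows(
    exon: GenomicInterval,
    strand: str,
    flank: int,
    chrom_len: int | None,
) -> dict[str, GenomicInterval]:
    """5'/3' junction windows of an exon, strand-aware."""
    out = {}
    for genomic_side, pos in (("left", exon.start), ("right", exon.end)):
        lo, hi = pos - flank, pos + flank
        if lo < 0 or (chrom_len is not None and hi > chrom_len):
            logger.debug("junction window at %s:%d clamped", exon.chrom, pos)
            lo = max(lo, 0)
            if chrom_len is not None:
                hi = min(hi, chrom_len)
        side = genomic_side
        out[side] = GenomicInterval(exon.chrom, lo, hi, strand)
    if strand == "-":
        return {"5p": out["right"], "3p": out["left"]}
    return {"5p": out["left"], "3p": out["right"]}


def extract_junction_windows(
    events: Sequence[ASEvent],
    flank: int = JUNCTION_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
) -> JunctionWindowSet:
    """Build splice-junction windows for alternative and constitutive exons.

    Each exon boundary (start and end) gets a window extending ``flank`` bp
    into both the exon and the flanking intron; windows are clamped at
    chromosome bounds.
    """
    if flank <= 0:
        raise SplicingError(f"flank must be positive, got {flank}")
    windows: list[JunctionWindow] = []
    for ev in events:
        chrom_len = chrom_sizes.get(ev.chrom) if chrom_sizes else None
        for side, win in _boundary_windows(
            ev.alt_exon, ev.strand, flank, chrom_len
        ).items():
            windows.append(JunctionWindow(ev.event_id, "alternative", side, win))
        for exon in ev.constitutive_exons:
            for side, win in _boundary_windows(
                exon, ev.strand, flank, chrom_len
            ).items():
                windows.append(JunctionWindow(ev.event_id, "constitutive", side, win))
    return JunctionWindowSet(windows, flank=flank, n_events=len(events))


@dataclass
class JunctionComparison:
    """Signal comparison between alternative and constitutive junctions."""

    n_events: int
    alt_mean: float
    const_mean: float
    mean_ratio: float  # alternative / constitutive
    t_alt_vs_const: float
    p_alt_vs_const: float
    side_tests: dict[str, tuple[float, float]]  # class -> (t, p) 5' vs 3'
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    per_event: pd.DataFrame | None = None


def compare_junction_signal(
    track: CoverageTrack,
    windows: JunctionWindowSet,
    bin_width: int = 10,
) -> JunctionComparison:
    """Compare mean junction signal between exon classes.

    Per event: the mean per-base signal over each of its junction windows,
    averaged within (class, side). Welch t-tests are reported for the 5' vs
    3' side within each class and for alternative vs constitutive (pooling
    both sides per event). Profiles are binned mean signal across windows,
    flipped so bin 0 is 5'-most.
    """
    if windows.n_events < 2:
        raise SplicingError("need >= 2 events for a junction comparison")
    rows = []
    for w in windows.windows:
        rows.append(
            {
                "event_id": w.event_id,
                "exon_class": w.exon_class,
                "side": w.side,
                "mean_signal": region_mean_signal(track, w.window),
            }
        )
    df = pd.DataFrame(rows)
    per_event = (
        df.groupby(["event_id", "exon_class", "side"])["mean_signal"]
        .mean()
        .reset_index()
    )

    def _values(exon_class: str, side: str | None = None) -> np.ndarray:
        sel = per_event["exon_class"] == exon_class
        if side is not None:
            sel &= per_event["side"] == side
        # pool per event so each event contributes one value
        return (
            per_event[sel].groupby("event_id")["mean_signal"].mean().to_numpy()
        )

    alt_vals = _values("alternative")
    const_vals = _values("constitutive")
    t_ac, p_ac = stats.ttest_ind(alt_vals, const_vals, equal_var=False)
    side_tests = {}
    for exon_class in ("alternative", "constitutive"):
        five = _values(exon_class, "5p")
        three = _values(exon_class, "3p")
        t, p = stats.ttest_ind(five, three, equal_var=False)
        side_tests[exon_class] = (float(t), float(p))

    profiles = {}
    for exon_class in ("alternative", "constitutive"):
        wins = [w for w in windows.windows if w.exon_class == exon_class]
        mats = []
        width = 2 * windows.flank
        n_bins = max(1, width // bin_width)
        for w in wins:
            vals = track.values(w.window.chrom, w.window.start, w.window.start + width)
            row = vals[: n_bins * bin_width].reshape(n_bins, -1).mean(axis=1)
            if w.window.strand == "-":
                row = row[::-1]
            mats.append(row)
        profiles[exon_class] = np.mean(mats, axis=0)

    const_mean = float(const_vals.mean())
    return JunctionComparison(
        n_events=windows.n_events,
        alt_mean=float(alt_vals.mean()),
        const_mean=const_mean,
        mean_ratio=float(alt_vals.mean() / const_mean) if const_mean else np.nan,
        t_alt_vs_const=float(t_ac),
        p_alt_vs_const=float(p_ac),
        side_tests=side_tests,
        profiles=profiles,
        per_event=per_event,
    )


def compare_junction_signal_multi(
    tracks: Mapping[str, CoverageTrack],
    windows: JunctionWindowSet,
    bin_width: int = 10,
) -> pd.DataFrame:
    """Run the junction comparison per mark; BH-adjust p across marks."""
    if not tracks:
        raise SplicingError("no tracks supplied")
    recs = []
    for name, track in tracks.items():
        cmp_ = compare_junction_signal(track, windows, bin_width=bin_width)
        recs.append(
            {
                "mark": name,
                "alt_mean": cmp_.alt_mean,
                "const_mean": cmp_.const_mean,
                "mean_ratio": cmp_.mean_ratio,
                "t": cmp_.t_alt_vs_const,
                "p": cmp_.p_alt_vs_const,
            }
        )
    out = pd.DataFrame(recs)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class ExonIntronDensity:
    exon_density: float
    intron_density: float
    ratio: float  # exon / intron
    t_statistic: float
    p_value: float
    per_exon: np.ndarray = field(repr=False, default=None)
    per_intron: np.ndarray = field(repr=False, default=None)


def exon_intron_density(
    track: CoverageTrack, features: FeatureSet
) -> ExonIntronDensity:
    """Mean signal density on exons vs introns, each feature weighted equally.

    Per-class density is the mean over features of the per-feature per-base
    mean, so multi-kilobase introns do not dominate the intron estimate.
    The ratio is exon density / intron density; a Welch t-test over the
    per-feature values tests the class difference.
    """
    if not features.exons:
        raise SplicingError("no exons in feature set")
    if not features.introns:
        raise SplicingError("no introns in feature set")
    per_exon = np.array([region_mean_signal(track, e) for e in features.exons])
    per_intron = np.array([region_mean_signal(track, i) for i in features.introns])
    exon_density = float(per_exon.mean())
    intron_density = float(per_intron.mean())
    t, p = stats.ttest_ind(per_exon, per_intron, equal_var=False)
    return ExonIntronDensity(
        exon_density=exon_density,
        intron_density=intron_density,
        ratio=exon_density / intron_density if intron_density else np.nan,
        t_statistic=float(t),
        p_value=float(p),
        per_exon=per_exon,
        per_intron=per_intron,
    )
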