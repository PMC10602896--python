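"""Base-resolution coverage tracks, CPM scaling and metaprofiles.

Tracks are held as dense per-chromosome float arrays (the package targets
desk-scale genomes), loaded from 4-column bedGraph or, when pyBigWig is
available, bigWig. Metaprofiles (reference-point and scaled gene-body) are
computed natively with mean-per-bin statistics; uncovered bases read as 0
and off-chromosome windows are clamped and zero-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class CoverageError(ValueError):
    """Raised on malformed coverage input or contract violations."""


@dataclass
class CoverageTrack:
    """Per-chromosome base-resolution signal with a normalization state."""

    chrom_arrays: dict[str, np.ndarray]
    total_count: float | None = None
    normalized: bool = False
    name: str = "track"

    def chrom_length(self, chrom: str) -> int:
        return len(self.chrom_arrays.get(chrom, ()))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions off the stored
        array (either side) read as 0."""
        if end <= start:
            raise CoverageError(f"empty query window {start}-{end}")
        arr = self.chrom_arrays.get(chrom)
        out = np.zeros(end - start, dtype=float)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: a * factor for c, a in self.chrom_arrays.items()},
            total_count=self.total_count,
            normalized=self.normalized,
            name=self.name,
        )


@dataclass
class SignalMatrix:
    """Binned signal per region; rows are strand-flipped to 5'->3'."""

    region_ids: list[str]
    matrix: np.ndarray  # shape (n_regions, n_bins)
    bin_labels: list[str] = field(default_factory=list)
    strand_flipped: bool = True

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = self.bin_labels or [str(i) for i in range(self.matrix.shape[1])]
        return pd.DataFrame(self.matrix, index=self.region_ids, columns=cols)


def load_coverage(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None, name: str = ""
) -> CoverageTrack:
    """Load a bedGraph (or bigWig, if pyBigWig is installed) coverage track.

    bedGraph intervals must be non-overlapping; overlaps raise
    :class:`CoverageError`. ``chrom_sizes`` fixes array lengths; otherwise
    each chromosome array ends at its last covered base.
    """
    path = Path(path)
    if path.suffix in {".bw", ".bigwig", ".bigWig"}:
        return _load_bigwig(path, name=name or path.stem)
    if path.suffix not in {".bedgraph", ".bg", ".bedGraph", ".txt", ".tsv"}:
        raise CoverageError(f"unrecognised coverage file suffix: {path.suffix!r}")
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if (df["value"] < 0).any():
        raise CoverageError(f"{path}: negative coverage values")
    arrays: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        if (starts[1:] < ends[:-1]).any():
            raise CoverageError(f"{path}: overlapping bedGraph intervals on {chrom}")
        size = (
            chrom_sizes[str(chrom)] if chrom_sizes is not None else int(ends.max())
        )
        arr = np.zeros(size, dtype=float)
        for s, e, v in zip(starts, ends, grp["value"].to_numpy(float)):
            arr[s : min(e, size)] = v
        arrays[str(chrom)] = arr
    return CoverageTrack(arrays, name=name or path.stem)


def _load_bigwig(path: Path, name: str) -> CoverageTrack:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise CoverageError("pyBigWig is required to read bigWig files") from exc
    bw = pyBigWig.open(str(path))
    arrays = {}
    for chrom, size in bw.chroms().items():
        vals = np.nan_to_num(np.array(bw.values(chrom, 0, size), dtype=float))
        if (vals < 0).any():
            raise CoverageError(f"{path}: negative coverage values")
        arrays[chrom] = vals
    bw.close()
    return CoverageTrack(arrays, name=name)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_arrays):
            arr = track.chrom_arrays[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def cpm_scale(track: CoverageTrack, total_count: float) -> CoverageTrack:
    """Counts-per-million normalization: v -> v * 1e6 / total_count."""
    if total_count <= 0:
        raise CoverageError(f"total_count must be > 0, got {total_count}")
    if track.normalized:
        raise CoverageError("track is already CPM-normalized")
    factor = 1e6 / total_count
    out = track.scaled(factor)
    out.total_count = total_count
    out.normalized = True
    return out


def region_mean_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Arithmetic mean of per-base signal over the interval."""
    if len(interval) <= 0:
        raise CoverageError("zero-length interval")
    return float(track.values(interval.chrom, interval.start, interval.end).mean())


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    return values.reshape(n_bins, -1).mean(axis=1)


def metaprofile_reference_point(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 2000,
    bin_width: int = 50,
    region_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Binned signal in ``[anchor - flank, anchor + flank)`` per anchor.

    Anchors are ``(chrom, position, strand)``. Rows of - strand anchors are
    reversed so bin 0 is always the 5' side; the mean profile is the column
    mean over rows. Windows running off the chromosome are clamped and
    zero-padded (logged).
    """
    if flank <= 0 or bin_width <= 0:
        raise CoverageError("flank and bin_width must be positive")
    if flank % bin_width != 0:
        raise CoverageError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    rows = np.empty((len(anchors), n_bins), dtype=float)
    for i, (chrom, pos, strand) in enumerate(anchors):
        start, end = pos - flank, pos + flank
        if start < 0 or end > track.chrom_length(chrom):
            logger.debug("anchor %s:%d window clamped and zero-padded", chrom, pos)
        vals = track.values(chrom, start, end)
        row = _bin_means(vals, n_bins)
        if strand == "-":
            row = row[::-1]
        rows[i] = row
    ids = list(region_ids) if region_ids is not None else [
        f"{c}:{p}:{s}" for c, p, s in anchors
    ]
    labels = [str(-flank + b * bin_width) for b in range(n_bins)]
    return SignalMatrix(ids, rows, bin_labels=labels)


def metaprofile_scaled_body(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bins: int = 40,
    region_ids: Sequence[str] | None = None,
) -> SignalMatrix:
    """Length-normalized gene-body profile with fixed-width flanks.

    Each region body is resampled to ``body_bins`` equal proportional spans
    (mean per span); flanks of ``flank`` bp are split into ``flank_bins``
    fixed-width bins. Rows for - strand regions are reversed. Bodies shorter
    than ``body_bins`` fall back to nearest-base assignment (logged).
    """
    if body_bins < 1:
        raise CoverageError("body_bins must be >= 1")
    if flank > 0 and (flank_bins < 1 or flank % flank_bins != 0):
        raise CoverageError("flank must be divisible by flank_bins")
    n_bins = body_bins + 2 * (flank_bins if flank > 0 else 0)
    rows = np.empty((len(regions), n_bins), dtype=float)
    for i, region in enumerate(regions):
        body = track.values(region.chrom, region.start, region.end)
        if len(body) < body_bins:
            logger.debug(
                "region %s:%d-%d shorter than body_bins; nearest-base bins",
                region.chrom, region.start, region.end,
            )
        # proportional spans: bin b covers [b*L/B, (b+1)*L/B)
        edges = np.floor(np.arange(body_bins + 1) * len(body) / body_bins).astype(int)
        body_prof = np.empty(body_bins)
        for b in range(body_bins):
            lo, hi = edges[b], edges[b + 1]
            if hi == lo:  # degenerate: nearest base
                lo = min(int(round(b * len(body) / body_bins)), len(body) - 1)
                hi = lo + 1
            body_prof[b] = body[lo:hi].mean()
        if flank > 0:
            left = _bin_means(
                track.values(region.chrom, region.start - flank, region.start),
                flank_bins,
            )
            right = _bin_means(
                track.values(region.chrom, region.end, region.end + flank),
                flank_bins,
            )
            row = np.concatenate([left, body_prof, right])
        else:
            row = body_prof
        if region.strand == "-":
            row = row[::-1]
        rows[i] = row
    ids = list(region_ids) if region_ids is not None else [
        f"{r.chrom}:{r.start}-{r.end}" for r in regions
    ]
    return SignalMatrix(ids, rows)
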