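"""Multi-track signal matrices and mark-mark Pearson correlation.

Replaces the multiBigwigSummary / plotCorrelation step natively: per-region
mean signal per track, product-moment correlation across tracks, and
average-linkage hierarchical grouping on 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .coverage import CoverageTrack, region_mean_signal
from .intervals import GenomicInterval


class CorrelationError(ValueError):
    pass


@dataclass
class MultiTrackMatrix:
    """Region x track matrix of mean signal (uncovered regions read 0)."""

    frame: pd.DataFrame  # index: region ids, columns: track names
    provenance: str = ""

    @property
    def track_names(self) -> list[str]:
        return list(self.frame.columns)


def build_signal_matrix(
    tracks: Mapping[str, CoverageTrack],
    regions: Sequence[GenomicInterval],
    region_ids: Sequence[str] | None = None,
    provenance: str = "",
) -> MultiTrackMatrix:
    """Mean signal of every track over every region, deterministic order."""
    names = list(tracks)
    if len(names) != len(set(names)):
        raise CorrelationError("duplicate track names")
    if len(names) < 2:
        raise CorrelationError("need >= 2 tracks")
    if len(regions) < 3:
        raise CorrelationError("need >= 3 regions")
    ids = (
        list(region_ids)
        if region_ids is not None
        else [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    )
    data = {
        name: [region_mean_signal(track, r) for r in regions]
        for name, track in tracks.items()
    }
    return MultiTrackMatrix(
        frame=pd.DataFrame(data, index=ids), provenance=provenance
    )


def pearson_correlation_matrix(matrix: MultiTrackMatrix) -> pd.DataFrame:
    """Product-moment correlation between track columns.

    Symmetric with unit diagonal; a zero-variance column is an error naming
    the track.
    """
    frame = matrix.frame
    stds = frame.std(ddof=0)
    for name, sd in stds.items():
        if sd == 0:
            raise CorrelationError(f"track {name!r} has zero variance")
    corr = np.corrcoef(frame.to_numpy().T)
    corr = (corr + corr.T) / 2  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=frame.columns, columns=frame.columns)


def correlation_pairs(corr: pd.DataFrame) -> pd.DataFrame:
    """Long-form upper-triangle pair list, sorted by descending r."""
    names = list(corr.columns)
    recs = [
        {"track_a": names[i], "track_b": names[j], "r": corr.iloc[i, j]}
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return (
        pd.DataFrame(recs)
        .sort_values("r", ascending=False)
        .reset_index(drop=True)
    )


def hierarchical_track_order(corr: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order on the distance 1 - r."""
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    return [corr.columns[i] for i in leaves_list(linkage)]
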