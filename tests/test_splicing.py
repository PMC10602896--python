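"""AS event parsing, junction windows and signal comparisons."""

import numpy as np
import pandas as pd
import pytest

from splicemark.annotation import FeatureSet, filter_splicing_features
from splicemark.coverage import CoverageTrack
from splicemark.intervals import GenomicInterval
from splicemark.splicing import (
    SplicingError,
    classify_significant_events,
    compare_junction_signal,
    compare_junction_signal_multi,
    events_from_frame,
    exon_intron_density,
    extract_junction_windows,
    parse_as_events,
)

from conftest import constant_track


def se_frame(rows):
    cols = [
        "ID", "GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
        "PValue", "FDR", "IncLevelDifference",
    ]
    return pd.DataFrame(rows, columns=cols)


def one_se(fdr=0.01, ild=0.3, event_id=0):
    return [event_id, "g1", "chr1", "+", 1000, 1200, 800, 900, 1400, 1500,
            fdr / 2, fdr, ild]


class TestParseAsEvents:
    def test_se_field_mapping_verbatim_zero_based(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        se_frame([one_se()]).to_csv(p, sep="\t", index=False)
        (ev,) = parse_as_events(p, "SE")
        assert (ev.alt_exon.start, ev.alt_exon.end) == (1000, 1200)
        assert {(e.start, e.end) for e in ev.constitutive_exons} == {
            (800, 900),
            (1400, 1500),
        }

    def test_missing_fdr_column_rejected(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        se_frame([one_se()]).drop(columns=["FDR"]).to_csv(p, sep="\t", index=False)
        with pytest.raises(SplicingError, match="FDR"):
            parse_as_events(p, "SE")

    def test_negative_inclusion_difference_means_control_inclusion(self):
        (ev,) = events_from_frame(se_frame([one_se(ild=-0.3)]), "SE")
        assert ev.inclusion_bias == "condition2"
        (ev,) = events_from_frame(se_frame([one_se(ild=0.3)]), "SE")
        assert ev.inclusion_bias == "condition1"

    def test_fdr_outside_unit_interval_rejected(self):
        with pytest.raises(SplicingError, match="FDR"):
            events_from_frame(se_frame([one_se(fdr=1.2)]), "SE")

    def test_exon_order_invariant_enforced(self):
        row = one_se()
        row[4], row[6] = 700, 800  # alt exon now starts before upstream ends
        row[5] = 750
        with pytest.raises(SplicingError, match="order"):
            events_from_frame(se_frame([row]), "SE")

    def test_ri_alternative_feature_is_the_retained_intron(self):
        df = pd.DataFrame(
            [{
                "ID": 0, "GeneID": "g1", "chr": "chr1", "strand": "+",
                "riExonStart_0base": 800, "riExonEnd": 1500,
                "upstreamES": 800, "upstreamEE": 900,
                "downstreamES": 1400, "downstreamEE": 1500,
                "PValue": 0.01, "FDR": 0.02, "IncLevelDifference": 0.2,
            }]
        )
        (ev,) = events_from_frame(df, "RI")
        assert (ev.alt_exon.start, ev.alt_exon.end) == (900, 1400)


class TestClassifySignificantEvents:
    @pytest.mark.parametrize(
        "fdr, significant", [(0.05, True), (0.051, False), (0.0, True)]
    )
    def test_boundary_inclusive_at_0_05(self, fdr, significant):
        events = events_from_frame(se_frame([one_se(fdr=fdr)]), "SE")
        counts, sig = classify_significant_events(events)
        assert counts["SE"] == int(significant)
        assert bool(sig) is significant

    def test_counts_reported_for_all_five_types(self):
        events = events_from_frame(
            se_frame([one_se(fdr=0.01, event_id=i) for i in range(3)]), "SE"
        )
        counts, _ = classify_significant_events(events)
        assert counts == {"SE": 3, "A5SS": 0, "A3SS": 0, "MXE": 0, "RI": 0}


class TestExtractJunctionWindows:
    def test_symmetric_windows_on_both_boundaries(self):
        events = events_from_frame(se_frame([one_se()]), "SE")
        ws = extract_junction_windows(events, flank=100)
        alt = {
            (w.side, w.window.start, w.window.end)
            for w in ws.windows
            if w.exon_class == "alternative"
        }
        assert alt == {("5p", 900, 1100), ("3p", 1100, 1300)}

    def test_minus_strand_swaps_sides(self):
        row = one_se()
        row[3] = "-"
        events = events_from_frame(se_frame([row]), "SE")
        ws = extract_junction_windows(events, flank=100)
        alt = {
            w.side: (w.window.start, w.window.end)
            for w in ws.windows
            if w.exon_class == "alternative"
        }
        assert alt == {"5p": (1100, 1300), "3p": (900, 1100)}

    def test_clamped_at_chromosome_start(self):
        row = one_se()
        row[4:10] = [50, 250, 0, 30, 400, 500]
        events = events_from_frame(se_frame([row]), "SE")
        ws = extract_junction_windows(events, flank=100, chrom_sizes={"chr1": 10_000})
        starts = [w.window.start for w in ws.windows]
        assert min(starts) == 0

    def test_nonpositive_flank_rejected(self):
        events = events_from_frame(se_frame([one_se()]), "SE")
        with pytest.raises(SplicingError, match="flank"):
            extract_junction_windows(events, flank=0)


def _events_on_grid(n, spacing=2000, noise_rng=None):
    rows = []
    for i in range(n):
        base = 1000 + i * spacing
        rows.append(
            [i, f"g{i}", "chr1", "+", base + 400, base + 600, base, base + 200,
             base + 1000, base + 1200, 0.001, 0.01, 0.3]
        )
    return events_from_frame(se_frame(rows), "SE")


class TestCompareJunctionSignal:
    def test_null_case_no_difference(self):
        events = _events_on_grid(50)
        ws = extract_junction_windows(events)
        rng = np.random.default_rng(3)
        track = CoverageTrack({"chr1": 2.0 + rng.normal(0, 0.2, 120_000)})
        cmp_ = compare_junction_signal(track, ws)
        assert cmp_.p_alt_vs_const > 0.05
        assert abs(cmp_.alt_mean - cmp_.const_mean) < 0.05

    def test_planted_depletion_detected(self):
        events = _events_on_grid(100)
        rng = np.random.default_rng(1)
        arr = 2.0 + rng.normal(0, 0.1, 250_000)
        for ev in events:
            arr[ev.alt_exon.start - 100 : ev.alt_exon.end + 100] *= 0.5
        track = CoverageTrack({"chr1": arr})
        ws = extract_junction_windows(events)
        cmp_ = compare_junction_signal(track, ws)
        assert cmp_.p_alt_vs_const < 0.01
        assert cmp_.mean_ratio == pytest.approx(0.5, abs=0.05)

    def test_single_event_rejected(self):
        ws = extract_junction_windows(_events_on_grid(1))
        with pytest.raises(SplicingError, match="2 events"):
            compare_junction_signal(constant_track(1.0, 100_000), ws)

    def test_minus_strand_profile_mirrors_plus(self):
        arr = np.arange(300_000, dtype=float)
        track = CoverageTrack({"chr1": arr})
        plus = compare_junction_signal(
            track, extract_junction_windows(_events_on_grid(3))
        )
        rows = []
        for i in range(3):
            base = 1000 + i * 2000
            rows.append(
                [i, f"g{i}", "chr1", "-", base + 400, base + 600, base,
                 base + 200, base + 1000, base + 1200, 0.001, 0.01, 0.3]
            )
        minus = compare_junction_signal(
            track, extract_junction_windows(events_from_frame(se_frame(rows), "SE"))
        )
        np.testing.assert_allclose(
            minus.profiles["alternative"],
            plus.profiles["alternative"][::-1],
            atol=1e-9,
        )

    def test_multi_track_bh_adjustment_monotone(self):
        events = _events_on_grid(40)
        ws = extract_junction_windows(events)
        rng = np.random.default_rng(2)
        tracks = {
            name: CoverageTrack({"chr1": 2.0 + rng.normal(0, 0.2, 100_000)})
            for name in ("m1", "m2", "m3")
        }
        out = compare_junction_signal_multi(tracks, ws)
        assert (out["p_bh"] >= out["p"] - 1e-12).all()
        assert set(out["mark"]) == {"m1", "m2", "m3"}


class TestExonIntronDensity:
    def _features(self):
        exons = [GenomicInterval("chr1", 1000 + i * 3000, 1300 + i * 3000, "+")
                 for i in range(10)]
        introns = [GenomicInterval("chr1", 1300 + i * 3000, 2500 + i * 3000, "+")
                   for i in range(10)]
        return FeatureSet(exons, introns, {})

    def test_uniform_track_gives_unit_ratio(self):
        dens = exon_intron_density(constant_track(2.5, 50_000), self._features())
        assert dens.ratio == 1.0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        track = CoverageTrack({"chr1": rng.uniform(0.5, 4, 50_000)})
        d1 = exon_intron_density(track, self._features())
        d2 = exon_intron_density(track.scaled(7.0), self._features())
        assert d2.exon_density == pytest.approx(7 * d1.exon_density, rel=1e-12)
        assert d2.intron_density == pytest.approx(7 * d1.intron_density, rel=1e-12)
        assert d2.ratio == pytest.approx(d1.ratio, rel=1e-12)

    def test_per_feature_weighting_removes_length_bias(self):
        # one long intron at high signal must not dominate the intron mean
        arr = np.ones(50_000)
        arr[10_000:30_000] = 9.0
        track = CoverageTrack({"chr1": arr})
        features = FeatureSet(
            exons=[GenomicInterval("chr1", 0, 200, "+")],
            introns=[
                GenomicInterval("chr1", 10_000, 30_000, "+"),  # long, signal 9
                GenomicInterval("chr1", 40_000, 40_600, "+"),  # short, signal 1
            ],
            provenance={},
        )
        dens = exon_intron_density(track, features)
        assert dens.intron_density == pytest.approx(5.0)  # equal weighting

    def test_empty_class_rejected(self):
        with pytest.raises(SplicingError, match="no exons"):
            exon_intron_density(
                constant_track(1.0), FeatureSet([], self._features().introns, {})
            )

    def test_standard_filters_feed_the_density(self, toy_genome):
        features = filter_splicing_features(
            (g.canonical for g in toy_genome.genes), 200, 500, True
        )
        assert all(len(e) >= 200 for e in features.exons)
        assert all(len(i) >= 500 for i in features.introns)
        first_exons = {
            (t.first_exon().start, t.first_exon().end)
            for g in toy_genome.genes
            for t in g.transcripts
        }
        assert not first_exons & {(e.start, e.end) for e in features.exons}
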