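"""Annotation ingest, intron/promoter derivation and location classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicemark.annotation import (
    AnnotationError,
    GeneModel,
    TranscriptModel,
    classify_genomic_location,
    define_promoters,
    derive_introns,
    filter_splicing_features,
    parse_gene_annotation,
    write_gtf,
)
from splicemark.intervals import GenomicInterval, IntervalIndex


def _gtf_line(chrom, start1, end1, strand, gene, tx):
    return (
        f'{chrom}\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\t'
        f'gene_id "{gene}"; transcript_id "{tx}";\n'
    )


@pytest.fixture()
def gtf_file(tmp_path):
    def _write(lines):
        p = tmp_path / "test.gtf"
        p.write_text("".join(lines))
        return p

    return _write


class TestParseGeneAnnotation:
    def test_one_based_closed_converted_to_zero_based_half_open(self, gtf_file):
        path = gtf_file(
            [
                _gtf_line("chr1", 101, 200, "+", "g1", "t1"),
                _gtf_line("chr1", 301, 400, "+", "g1", "t1"),
            ]
        )
        (gene,) = parse_gene_annotation(path)
        assert [(e.start, e.end) for e in gene.canonical.exons] == [
            (100, 200),
            (300, 400),
        ]

    def test_minus_strand_canonical_tss_is_five_prime_most(self, gtf_file):
        path = gtf_file(
            [
                _gtf_line("chr1", 101, 200, "-", "g1", "t1"),
                _gtf_line("chr1", 301, 400, "-", "g1", "t1"),
            ]
        )
        (gene,) = parse_gene_annotation(path)
        assert gene.canonical_tss == 400

    def test_missing_transcript_id_names_line_number(self, gtf_file):
        path = gtf_file(
            [
                _gtf_line("chr1", 101, 200, "+", "g1", "t1"),
                'chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g2";\n',
            ]
        )
        with pytest.raises(AnnotationError, match="line 2"):
            parse_gene_annotation(path)

    def test_end_before_start_rejected_with_line_number(self, gtf_file):
        path = gtf_file([_gtf_line("chr1", 200, 100, "+", "g1", "t1")])
        with pytest.raises(AnnotationError, match="line 1"):
            parse_gene_annotation(path)

    def test_canonical_is_longest_exonic_with_lexicographic_ties(self, gtf_file):
        path = gtf_file(
            [
                _gtf_line("chr1", 101, 200, "+", "g1", "tB"),
                _gtf_line("chr1", 101, 300, "+", "g1", "tA"),
                _gtf_line("chr1", 401, 600, "+", "g1", "tC"),
            ]
        )
        (gene,) = parse_gene_annotation(path)
        # tA and tC both span 200 exonic bases; tie broken lexicographically
        assert gene.canonical_transcript_id == "tA"

    def test_round_trip_preserves_coordinates(self, tmp_path, toy_genome):
        out = tmp_path / "rt.gtf"
        write_gtf(toy_genome.genes, out)
        reparsed = parse_gene_annotation(out)
        orig = {
            (g.gene_id, t.transcript_id): [(e.start, e.end) for e in t.exons]
            for g in toy_genome.genes
            for t in g.transcripts
        }
        again = {
            (g.gene_id, t.transcript_id): [(e.start, e.end) for e in t.exons]
            for g in reparsed
            for t in g.transcripts
        }
        assert orig == again


class TestDeriveIntrons:
    @pytest.mark.parametrize(
        "exons, expected",
        [
            ([(100, 200), (300, 400)], [(200, 300)]),
            ([(100, 200)], []),
            ([(0, 50), (60, 100), (150, 200)], [(50, 60), (100, 150)]),
        ],
    )
    def test_gaps_between_exons(self, exons, expected):
        tx = TranscriptModel(
            "t1", [GenomicInterval("chr1", s, e, "+") for s, e in exons], "+"
        )
        assert [(i.start, i.end) for i in derive_introns(tx)] == expected

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlap"):
            TranscriptModel(
                "t1",
                [
                    GenomicInterval("chr1", 0, 100, "+"),
                    GenomicInterval("chr1", 50, 150, "+"),
                ],
                "+",
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        lengths=st.lists(
            st.tuples(st.integers(1, 300), st.integers(1, 500)),
            min_size=1,
            max_size=8,
        )
    )
    def test_exons_and_introns_tile_the_transcript_span(self, lengths):
        """Exons plus derived introns cover the span with no gap/overlap."""
        pos, exons = 10, []
        for exon_len, gap in lengths:
            exons.append(GenomicInterval("chr1", pos, pos + exon_len, "+"))
            pos += exon_len + gap
        tx = TranscriptModel("t1", exons, "+")
        pieces = sorted(exons + derive_introns(tx), key=lambda iv: iv.start)
        assert pieces[0].start == tx.start and pieces[-1].end == tx.end
        for a, b in zip(pieces, pieces[1:]):
            assert a.end == b.start


def _single_exon_gene(gene_id, chrom, start, end, strand):
    tx = TranscriptModel(
        f"{gene_id}.t", [GenomicInterval(chrom, start, end, strand)], strand
    )
    return GeneModel(gene_id, strand, [tx])


class TestDefinePromoters:
    def test_plus_strand_window(self):
        gene = _single_exon_gene("g", "chr1", 5000, 6000, "+")
        prom = define_promoters([gene], 2000, 2000, {"chr1": 100_000})
        assert (prom["g"].start, prom["g"].end) == (3000, 7000)

    def test_clamped_at_chromosome_start(self):
        gene = _single_exon_gene("g", "chr1", 500, 1500, "+")
        prom = define_promoters([gene], 2000, 500, {"chr1": 100_000})
        assert (prom["g"].start, prom["g"].end) == (0, 1000)

    def test_minus_strand_clamped_both_ends(self):
        gene = _single_exon_gene("g", "chr1", 100, 400, "-")
        prom = define_promoters([gene], 2000, 2000, {"chr1": 1000})
        assert (prom["g"].start, prom["g"].end) == (0, 1000)

    def test_unknown_chromosome_rejected(self):
        gene = _single_exon_gene("g", "chrX", 5000, 6000, "+")
        with pytest.raises(AnnotationError, match="chrX"):
            define_promoters([gene], 2000, 2000, {"chr1": 100_000})

    def test_zero_width_window_rejected(self):
        gene = _single_exon_gene("g", "chr1", 5000, 6000, "+")
        with pytest.raises(ValueError):
            define_promoters([gene], 0, 0)


class TestFilterSplicingFeatures:
    def _tx(self, exon_spans, strand="+"):
        return TranscriptModel(
            "t1",
            [GenomicInterval("chr1", s, e, strand) for s, e in exon_spans],
            strand,
        )

    def test_first_exon_removed_then_length_filter(self):
        # lengths 150, 300, 250: the 150 bp exon is also the first exon
        tx = self._tx([(0, 150), (1000, 1300), (2500, 2750)])
        fs = filter_splicing_features([tx], 200, 500, drop_first_exon=True)
        assert sorted(len(e) for e in fs.exons) == [250, 300]

    def test_first_exon_is_strand_aware(self):
        tx = self._tx([(0, 300), (1000, 1300), (2500, 2800)], strand="-")
        fs = filter_splicing_features([tx], 200, 500, drop_first_exon=True)
        # on - strand the 5'-most exon is the genomically last one
        assert {(e.start, e.end) for e in fs.exons} == {(0, 300), (1000, 1300)}

    def test_short_intron_dropped(self):
        tx = self._tx([(0, 300), (700, 1000), (1600, 1900)])
        fs = filter_splicing_features([tx], 200, 500, drop_first_exon=False)
        # first gap is 400 bp (< 500), second is 600 bp
        assert [(i.start, i.end) for i in fs.introns] == [(1000, 1600)]

    def test_all_filtered_out_is_an_error(self):
        tx = self._tx([(0, 100), (200, 290)])
        with pytest.raises(AnnotationError, match="no features"):
            filter_splicing_features([tx], 200, 500, drop_first_exon=True)

    def test_provenance_records_parameters(self):
        tx = self._tx([(0, 300), (1000, 1300)])
        fs = filter_splicing_features([tx], 200, 500, drop_first_exon=True)
        assert fs.provenance["min_exon_len"] == 200
        assert fs.provenance["min_intron_len"] == 500
        assert fs.provenance["drop_first_exon"] is True


class TestClassifyGenomicLocation:
    def test_promoter_wins_over_exon(self):
        promoters = IntervalIndex.build([GenomicInterval("chr1", 0, 500)])
        exons = IntervalIndex.build([GenomicInterval("chr1", 400, 800)])
        introns = IntervalIndex.build([])
        q = GenomicInterval("chr1", 450, 460)
        assert classify_genomic_location(q, promoters, exons, introns) == "promoter"

    def test_intron_only(self):
        idx = IntervalIndex.build([])
        introns = IntervalIndex.build([GenomicInterval("chr1", 100, 900)])
        q = GenomicInterval("chr1", 150, 160)
        assert classify_genomic_location(q, idx, idx, introns) == "intron"

    def test_feature_free_chromosome_is_intergenic(self):
        idx = IntervalIndex.build([GenomicInterval("chr1", 0, 100)])
        q = GenomicInterval("chr9", 0, 10)
        assert classify_genomic_location(q, idx, idx, idx) == "intergenic"

    def test_agrees_with_per_base_scan_oracle(self):
        rng = np.random.default_rng(5)
        genome_len = 2000
        def random_ivs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, genome_len - 10))
                out.append(GenomicInterval("c", s, s + int(rng.integers(1, 50))))
            return out

        proms, exons, introns = random_ivs(5), random_ivs(8), random_ivs(8)
        pi, ei, ii = (IntervalIndex.build(x) for x in (proms, exons, introns))
        # brute-force: label per base, query label = highest-precedence base
        base = np.zeros(genome_len, dtype=int)  # 0 intergenic
        for rank, ivs in ((1, introns), (2, exons), (3, proms)):
            for iv in ivs:
                base[iv.start : iv.end] = np.maximum(base[iv.start : iv.end], rank)
        labels = {0: "intergenic", 1: "intron", 2: "exon", 3: "promoter"}
        for _ in range(200):
            s = int(rng.integers(0, genome_len - 20))
            q = GenomicInterval("c", s, s + int(rng.integers(1, 20)))
            expected = labels[int(base[q.start : q.end].max())]
            assert classify_genomic_location(q, pi, ei, ii) == expected
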