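"""Splicing-chromatin integration: the core comparison.

Selects significant AS events (FDR <= 0.05) from the emitted rMATS-style
tables, builds +/-100 bp splice-junction windows, compares signal between
alternative and constitutive skipped exons for each mark, computes
exon/intron signal densities under the standard feature filters, and
correlates the marks over the significant junction windows. Writes tables
under results/splicing/ and prints what it finds: on this dataset the
methylarginine-like marks carry ~3x exonic enrichment and a planted 2x
depletion at alternative-exon junctions that the active mark lacks.
"""

import json
from pathlib import Path

import pandas as pd

from splicemark.annotation import (
    filter_splicing_features,
    parse_gene_annotation,
    read_chrom_sizes,
)
from splicemark.correlation import (
    build_signal_matrix,
    correlation_pairs,
    hierarchical_track_order,
    pearson_correlation_matrix,
)
from splicemark.coverage import load_coverage
from splicemark.simulate import TruthManifest
from splicemark.splicing import (
    classify_significant_events,
    compare_junction_signal,
    exon_intron_density,
    extract_junction_windows,
    parse_as_events,
)

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "dataset"
OUT = BASE / "splicing"
MARKS = ("H4R3me2a", "H4R3me2s", "H3K4me3")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = TruthManifest.from_json(DATA / "manifest.json")
    chrom_sizes = read_chrom_sizes(DATA / "chrom.sizes")
    genes = parse_gene_annotation(DATA / "annotation.gtf")
    tracks = {
        mark: load_coverage(DATA / f"{mark}.bedgraph", chrom_sizes)
        for mark in MARKS
    }

    counts_all = {}
    for etype in ("SE", "A5SS", "A3SS", "MXE", "RI"):
        events = parse_as_events(DATA / f"{etype}.MATS.JC.txt", etype)
        counts, _ = classify_significant_events(events)
        counts_all[etype] = counts[etype]
        truth = len(manifest.significant_event_ids[etype])
        print(f"{etype}: {counts[etype]} significant events (planted {truth})")

    se_events = parse_as_events(DATA / "SE.MATS.JC.txt", "SE")
    _, significant = classify_significant_events(se_events)
    windows = extract_junction_windows(significant, flank=100,
                                       chrom_sizes=chrom_sizes)

    features = filter_splicing_features(
        (g.canonical for g in genes), min_exon_len=200, min_intron_len=500,
        drop_first_exon=True,
    )
    jrows, drows = [], []
    for mark, track in tracks.items():
        cmp_ = compare_junction_signal(track, windows)
        jrows.append(
            {"mark": mark, "alt_mean": round(cmp_.alt_mean, 4),
             "const_mean": round(cmp_.const_mean, 4),
             "mean_ratio": round(cmp_.mean_ratio, 4),
             "t": round(cmp_.t_alt_vs_const, 3),
             "p": cmp_.p_alt_vs_const}
        )
        dens = exon_intron_density(track, features)
        drows.append(
            {"mark": mark, "exon_density": round(dens.exon_density, 4),
             "intron_density": round(dens.intron_density, 4),
             "ratio": round(dens.ratio, 4), "p": dens.p_value}
        )
        print(
            f"{mark}: junction alt/const ratio {cmp_.mean_ratio:.3f} "
            f"(p={cmp_.p_alt_vs_const:.2e}); exon:intron ratio "
            f"{dens.ratio:.3f}"
        )
    pd.DataFrame(jrows).to_csv(OUT / "junction_comparison.tsv", sep="\t", index=False)
    pd.DataFrame(drows).to_csv(OUT / "exon_intron_density.tsv", sep="\t", index=False)

    regions = [w.window for w in windows.windows]
    mat = build_signal_matrix(
        tracks, regions, provenance="significant SE junction windows"
    )
    corr = pearson_correlation_matrix(mat)
    corr.to_csv(OUT / "mark_correlation.tsv", sep="\t")
    order = hierarchical_track_order(corr)
    pairs = correlation_pairs(corr)
    print("mark correlation (average-linkage order):", " -> ".join(order))
    print(pairs.to_string(index=False))

    summary = {
        "significant_events": counts_all,
        "planted_delta": manifest.delta,
        "planted_rho": manifest.rho,
        "junction": {r["mark"]: r["mean_ratio"] for r in jrows},
        "exon_intron_ratio": {r["mark"]: r["ratio"] for r in drows},
        "correlation_order": order,
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
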