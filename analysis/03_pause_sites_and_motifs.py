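"""Differential pause calling, positional statistics and stall motifs.

Replicate-paired Fisher tests call codons with differential ribosome
occupancy between euploid and aneuploid; replicate calls are combined by
union with direction-conflict exclusion. The script then scores recovery
of the planted stalls, tests the peak-position shift between directions
(Wilcoxon), asks whether peak transcripts are enriched on the duplicated
chromosome (hypergeometric), and runs the flanking-residue enrichment,
which should recover lysine/asparagine at the P site and glycine/
glutamate at the A site.
"""

import argparse
from pathlib import Path

import pandas as pd

from ribopause import annotation, evaluation, motifs, occupancy, pausing


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    models, _ = annotation.load_gene_models(
        args.datadir / "models/genes.gff3", args.datadir / "models/genome.fa"
    )
    samples = pd.read_csv(args.datadir / "ribo_samples.tsv", sep="\t")
    matrices = {
        s: occupancy.PSiteCountMatrix.from_frame(
            pd.read_csv(args.datadir / f"ribo_counts_{s}.tsv", sep="\t"), s
        )
        for s in samples["sample"]
    }
    genes = sorted(occupancy.retained_intersection(matrices.values(), 50))

    correlations = []
    results = []
    for rep in sorted(samples["replicate"].unique()):
        e, a = matrices[f"euploid_rep{rep}"], matrices[f"aneuploid_rep{rep}"]
        te, _ = occupancy.normalize_occupancy(e)
        ta, _ = occupancy.normalize_occupancy(a)
        correlations.append(pausing.correlate_all(te, ta, genes, replicate=rep))
        results.append(pausing.call_peaks(e, a, genes, alpha=args.alpha, replicate=rep))
    corr = pd.concat(correlations, ignore_index=True)
    corr.to_csv(args.outdir / "trace_correlations.tsv", sep="\t", index=False)
    print(
        f"paired occupancy-trace correlations over {len(genes)} genes: "
        f"median {corr['correlation'].median():.3f}"
    )

    combined = pausing.combine_replicates(results)
    combined.peaks.to_csv(args.outdir / "peaks.tsv", sep="\t", index=False)
    combined.summary.to_csv(args.outdir / "peak_summary.tsv", sep="\t", index=False)
    print(combined.summary.to_string(index=False))
    if len(combined.conflicts):
        print(f"{len(combined.conflicts)} codons dropped for conflicting directions")

    truth = pd.read_csv(args.datadir / "truth_ribo/truth_stalls.tsv", sep="\t")
    score = evaluation.score_stall_recovery(combined.peaks, truth)
    print(
        f"planted-stall recovery: {score['n_recovered']}/{score['n_planted']} "
        f"(sensitivity {score['sensitivity']:.2f}), "
        f"direction accuracy {score['direction_accuracy']:.2f}"
    )

    pos_a = combined.peaks.loc[
        combined.peaks["direction"] == pausing.ANEUPLOID_HIGHER, "relative_position"
    ]
    pos_e = combined.peaks.loc[
        combined.peaks["direction"] == pausing.EUPLOID_HIGHER, "relative_position"
    ]
    if len(pos_a) and len(pos_e):
        _, p = pausing.peak_position_test(pos_a, pos_e)
        print(
            f"peak positions: aneuploid-higher median {pos_a.median():.2f} vs "
            f"euploid-higher {pos_e.median():.2f} (rank-sum p = {p:.3g})"
        )

    gene_to_chrom = {g: m.chromosome for g, m in models.items()}
    duplicated = pd.read_csv(
        args.datadir / "truth_ribo/truth_genes.tsv", sep="\t"
    )["chromosome"].iloc[0]
    peak_genes = combined.peaks.loc[
        combined.peaks["direction"] == pausing.ANEUPLOID_HIGHER, "gene_id"
    ].unique()
    p_chrom = pausing.chromosome_enrichment(
        peak_genes, genes, gene_to_chrom, "chr01"
    )
    print(
        f"duplicated-chromosome enrichment among aneuploid-higher peak "
        f"transcripts: hypergeometric p = {p_chrom:.3f} "
        "(stalls are planted uniformly, so no enrichment is expected here)"
    )

    proteins = {g: m.protein for g, m in models.items()}
    background = annotation.build_proteome(proteins)
    aneu_peaks = combined.peaks[
        combined.peaks["direction"] == pausing.ANEUPLOID_HIGHER
    ]
    enrich = motifs.position_enrichment(
        motifs.extract_flanks(aneu_peaks, proteins), background
    )
    enrich.to_csv(args.outdir / "motif_enrichment.tsv", sep="\t", index=False)
    top = (
        enrich[enrich["significant"] & enrich["position"].isin([0, 1])]
        .sort_values("fdr")
        .head(6)
    )
    print("top significant stall-site residues (position 0 = P site, 1 = A site):")
    print(
        top[["position", "symbol", "log2_enrichment", "fdr"]]
        .round({"log2_enrichment": 2})
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
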