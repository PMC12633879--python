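"""Generate the synthetic study datasets.

Builds the three datasets the downstream analyses consume, each with
ground-truth records: (1) ribosome-profiling P-site counts for euploid and
aneuploid replicates with 200 planted 8-fold stall sites (K/N P-site, G/E
A-site residues) and a 2.0x duplicated chromosome; (2) spike-in RNA-seq
counts for a euploid and four aneuploids across log phase and day 1 with
100 planted silencing-defect genes; (3) barcode-screen counts with 10
early-benefit and 10 lifespan-specific planted hits.

Writes FASTA/GFF3/TSV under results/data/.
"""

import argparse
from pathlib import Path

from ribopause import annotation, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    config = simulate.SimConfig(seed=args.seed, depth=800_000)
    genome = simulate.generate_genome(config)
    annotation.write_gene_models(genome.models, genome.chromosomes, out / "models")
    sim = simulate.simulate_footprints(genome)
    for sample, matrix in sim.matrices.items():
        matrix.to_frame().to_csv(out / f"ribo_counts_{sample}.tsv", sep="\t", index=False)
    sim.sample_sheet.to_csv(out / "ribo_samples.tsv", sep="\t", index=False)
    sim.truth.write(out / "truth_ribo")
    print(
        f"ribosome profiling: {len(genome.models)} genes on "
        f"{config.n_chromosomes} chromosomes ({config.duplicated_chromosome} "
        f"duplicated {config.dosage_fold}x), "
        f"{len(genome.truth.stall_sites)} planted stalls, "
        f"{len(sim.matrices)} samples x {config.depth:,} footprints"
    )

    spike = simulate.simulate_spikein(simulate.SpikeConfig(), seed=args.seed)
    spike.counts.to_csv(out / "rna_counts.tsv", sep="\t")
    spike.sample_sheet.to_csv(out / "rna_samples.tsv", sep="\t", index=False)
    Path(out / "rna_spike_genes.txt").write_text("\n".join(spike.spike_genes) + "\n")
    spike.truth.write(out / "truth_rna")
    print(
        f"RNA-seq: {spike.counts.shape[0]} genes x {spike.counts.shape[1]} samples, "
        f"{len(spike.spike_genes)} spike-ins, "
        f"{len(spike.truth.silencing_defect_genes)} planted silencing-defect genes "
        f"(reference {spike.reference_sample})"
    )

    scr = simulate.simulate_screen(simulate.ScreenConfig(), seed=args.seed)
    scr.counts.to_csv(out / "screen_counts.tsv", sep="\t")
    scr.sample_sheet.to_csv(out / "screen_samples.tsv", sep="\t", index=False)
    scr.truth.write(out / "truth_screen")
    n_hits = scr.truth.screen_hits["class"].value_counts().to_dict()
    print(f"screen: {scr.counts.shape[0]} genes x {scr.counts.shape[1]} samples, planted hits {n_hits}")


if __name__ == "__main__":
    main()
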