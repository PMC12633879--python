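"""Occupancy QC and chromosome dosage.

Reloads the simulated profiling data through the annotation and occupancy
layers exactly as real data would flow (GFF3 + FASTA -> gene models;
count tables -> matrices), normalizes occupancy, applies the >= 50
body-read gene filter, and summarises the per-chromosome median fold
difference in read share between aneuploid and euploid. The duplicated
chromosome should read out near the simulated 2.0x dosage.
"""

import argparse
from pathlib import Path

import pandas as pd

from ribopause import annotation, occupancy


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    models, exclusions = annotation.load_gene_models(
        args.datadir / "models/genes.gff3", args.datadir / "models/genome.fa"
    )
    print(f"gene models: {len(models)} included, {len(exclusions)} excluded")

    samples = pd.read_csv(args.datadir / "ribo_samples.tsv", sep="\t")
    matrices = {}
    for sample in samples["sample"]:
        frame = pd.read_csv(args.datadir / f"ribo_counts_{sample}.tsv", sep="\t")
        matrices[sample] = occupancy.PSiteCountMatrix.from_frame(frame, sample)
    retained = occupancy.retained_intersection(matrices.values(), 50)
    print(f"{len(retained)} genes retained at >= 50 body reads in every sample")

    gene_to_chrom = {g: m.chromosome for g, m in models.items()}
    rows = []
    for rep in sorted(samples["replicate"].unique()):
        med = occupancy.chromosome_dosage(
            matrices[f"euploid_rep{rep}"],
            matrices[f"aneuploid_rep{rep}"],
            gene_to_chrom,
            genes=sorted(retained),
        )
        rows.append(med.rename(f"rep{rep}"))
    dosage = pd.concat(rows, axis=1)
    args.outdir.mkdir(parents=True, exist_ok=True)
    dosage.to_csv(args.outdir / "chromosome_dosage.tsv", sep="\t")
    print("per-chromosome median fold (aneuploid/euploid read share):")
    print(dosage.round(3).to_string())

    traces, skipped = occupancy.normalize_occupancy(matrices["euploid_rep1"])
    print(
        f"normalized occupancy for {len(traces)} genes "
        f"({len(skipped)} skipped as too short); body means all 1 by construction"
    )


if __name__ == "__main__":
    main()
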