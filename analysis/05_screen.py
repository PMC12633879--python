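"""Barcode-screen hit selection and classification.

TMM-normalizes the screen counts, scores day-1 and day-28 enrichment
versus the starting pool in each strain, selects genes significantly
enriched in the aneuploid at day 28 with at least a 2-fold linear
advantage over the euploid, and splits hits into lifespan-specific
(> 2-fold more enriched at d28 than d1) versus early-benefit classes.
Recovery is scored against the planted hits.
"""

import argparse
from pathlib import Path

import pandas as pd

from ribopause import evaluation, screen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.1)
    ap.add_argument("--fold", type=float, default=2.0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.datadir / "screen_counts.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(args.datadir / "screen_samples.tsv", sep="\t")
    factors = screen.tmm_factors(counts)
    factors.rename_axis("sample").to_csv(args.outdir / "tmm_factors.tsv", sep="\t")

    scores = {}
    for strain in ("aneuploid", "euploid"):
        for tp in ("d1", "d28"):
            s = screen.enrichment_scores(counts, sheet, strain, tp, factors=factors)
            s.to_csv(
                args.outdir / f"screen_scores_{strain}_{tp}.tsv", sep="\t", index=False
            )
            scores[(strain, tp)] = s

    hits = screen.select_hits(
        scores[("aneuploid", "d28")],
        scores[("euploid", "d28")],
        fdr_cut=args.fdr,
        fold_cut=args.fold,
    )
    classified = screen.classify_hits(
        hits, scores[("aneuploid", "d1")], scores[("aneuploid", "d28")], args.fold
    )
    classified.to_csv(args.outdir / "screen_hits.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.datadir / "truth_screen/truth_screen_hits.tsv", sep="\t")
    score = evaluation.score_screen_hits(classified, truth)
    by_class = classified["class"].value_counts().to_dict()
    print(
        f"selected {score['n_hits']} hits at FDR < {args.fdr} with >= "
        f"{args.fold}-fold aneuploid advantage: {by_class}"
    )
    print(
        f"planted-hit recovery: {score['n_true_hits']}/{score['n_planted']} "
        f"(sensitivity {score['sensitivity']:.2f}), "
        f"{score['n_false_hits']} false hits, "
        f"class accuracy {score['class_accuracy']:.2f}"
    )


if __name__ == "__main__":
    main()
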