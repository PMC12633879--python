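"""Barcode-screen enrichment: TMM normalization and the hit cascade.

Samples are normalized with trimmed-mean-of-M-values factors. Genes with a
significantly positive log2 enrichment at day 28 versus the starting pool
in the aneuploid, and at least a 2-fold linear difference in enrichment
over the euploid, are selected as hits; hits more than 2-fold more
enriched at day 28 than day 1 are classified lifespan-specific, the rest
early-benefit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, moderated_two_sample

LIFESPAN_SPECIFIC = "lifespan_specific"
EARLY_BENEFIT = "early_benefit"


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Doubly trimmed (30% on log-ratios M, 5% on average abundance A),
    precision-weighted mean of M against a reference sample (by default the
    sample whose upper quartile of scaled counts is closest to the mean
    upper quartile), with the factors rescaled to geometric mean 1.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"sample(s) with no counts: {bad}")
    if reference is None:
        q75 = np.array(
            [np.quantile(y[:, j][y[:, j] > 0], 0.75) / lib[j] for j in range(y.shape[1])]
        )
        ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_j = counts.columns.get_loc(reference)
    yr, nr = y[:, ref_j], lib[ref_j]
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        yk, nk = y[:, j], lib[j]
        pos = (yk > 0) & (yr > 0)
        if not pos.any():
            continue
        m = np.log2((yk[pos] / nk) / (yr[pos] / nr))
        a = 0.5 * np.log2((yk[pos] / nk) * (yr[pos] / nr))
        w = (nk - yk[pos]) / (nk * yk[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _normalized_log(counts: pd.DataFrame, factors: pd.Series, pseudocount: float):
    lib = counts.sum(axis=0)
    effective = lib * factors.reindex(counts.columns)
    cpm = counts.div(effective, axis=1) * 1e6
    return np.log2(cpm + pseudocount)


def enrichment_scores(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    strain: str,
    timepoint: str,
    baseline: str = "pool",
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 enrichment of ``timepoint`` vs the starting pool.

    Abundances are TMM-normalized counts per million; the p-value comes
    from the built-in moderated two-sample test across replicates (an
    external engine's per-gene stats can be substituted downstream), with
    BH correction across genes.
    """
    if factors is None:
        factors = tmm_factors(counts)
    log_cpm = _normalized_log(counts, factors, pseudocount)
    sheet = sample_sheet.set_index("sample")

    def _cols(tp):
        sel = sheet[(sheet["strain"] == strain) & (sheet["timepoint"] == tp)].index
        if len(sel) == 0:
            raise ValueError(f"no samples for strain={strain!r} timepoint={tp!r}")
        return sel

    target = log_cpm[_cols(timepoint)].to_numpy()
    pool = log_cpm[_cols(baseline)].to_numpy()
    delta, p = moderated_two_sample(target, pool)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "strain": strain,
            "timepoint": timepoint,
            "log2fc": delta,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )


def select_hits(
    aneuploid_scores: pd.DataFrame,
    euploid_scores: pd.DataFrame,
    fdr_cut: float = 0.1,
    fold_cut: float = 2.0,
) -> pd.DataFrame:
    """Aneuploid-specific enriched genes.

    A gene is a hit iff its aneuploid day-28 enrichment is significantly
    positive (log2fc > 0, fdr < ``fdr_cut``) and the linear difference in
    enrichment over the euploid, 2**(aneuploid log2fc - euploid log2fc), is
    at least ``fold_cut``.
    """
    a = aneuploid_scores.set_index("gene_id")
    e = euploid_scores.set_index("gene_id")
    shared = a.index.intersection(e.index)
    a, e = a.loc[shared], e.loc[shared]
    diff = a["log2fc"] - e["log2fc"]
    selected = (a["log2fc"] > 0) & (a["fdr"] < fdr_cut) & (2.0**diff >= fold_cut)
    out = pd.DataFrame(
        {
            "gene_id": shared,
            "aneuploid_log2fc": a["log2fc"].to_numpy(),
            "euploid_log2fc": e["log2fc"].to_numpy(),
            "aneuploid_fdr": a["fdr"].to_numpy(),
            "linear_differential": (2.0**diff).to_numpy(),
        }
    )
    return out[selected.to_numpy()].reset_index(drop=True)


def classify_hits(
    hits: pd.DataFrame,
    d1_scores: pd.DataFrame,
    d28_scores: pd.DataFrame,
    fold_cut: float = 2.0,
) -> pd.DataFrame:
    """Split hits into lifespan-specific vs early-benefit classes.

    A hit is lifespan-specific iff its aneuploid enrichment is more than
    ``fold_cut``-fold greater at day 28 than at day 1
    (2**(log2fc_d28 - log2fc_d1) > fold_cut); otherwise early-benefit.
    """
    d1 = d1_scores.set_index("gene_id")["log2fc"]
    d28 = d28_scores.set_index("gene_id")["log2fc"]
    missing = [g for g in hits["gene_id"] if g not in d1.index or g not in d28.index]
    if missing:
        raise ValueError(f"hits not present in the scored tables: {missing[:5]}")
    late_fold = 2.0 ** (
        d28.loc[hits["gene_id"]].to_numpy() - d1.loc[hits["gene_id"]].to_numpy()
    )
    out = hits.copy()
    out["d28_vs_d1_fold"] = late_fold
    out["class"] = np.where(late_fold > fold_cut, LIFESPAN_SPECIFIC, EARLY_BENEFIT)
    return out
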