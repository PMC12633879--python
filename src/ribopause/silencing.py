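"""Spike-in normalization and the transcriptome-silencing selection rule.

Per-cell abundances are obtained by scaling each sample so that the slope
of its foreign spike-in counts against a reference sample equals 1. The
silencing-defect gene set is then those genes significantly repressed in
the euploid on quiescence entry (relative to euploid log phase) yet
significantly higher than the euploid in every aneuploid strain at at
least one timepoint.

The differential engine is pluggable: the built-in moderated two-sample
test on log-scale normalized counts covers synthetic data end-to-end, and
externally computed per-gene statistics in the same long format are
accepted anywhere a stats table is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, moderated_two_sample, weighted_median

MIN_SPIKE_GENES = 5

EUPLOID_REPRESSION = "euploid_repression"
ANEUPLOID_VS_EUPLOID = "aneuploid_vs_euploid"

STATS_COLUMNS = ["gene_id", "kind", "strain", "timepoint", "log2fc", "p_value", "fdr"]


class NormalizationError(ValueError):
    pass


@dataclass
class SpikeNormFactors:
    factors: pd.Series  # per-sample positive scale factors, reference == 1
    reference: str
    diagnostics: pd.DataFrame  # sample, slope, n_spikes, residual_spread


def _slope(x: np.ndarray, y: np.ndarray, method: str, trim: float) -> float:
    """Through-origin slope of y against x under three conventions.

    ``log``: trimmed mean of log ratios (efficient for multiplicative
    noise); ``lad``: exact least-absolute-deviation through-origin fit (the
    weighted median of ratios); ``ols``: least squares through the origin.
    """
    if method == "ols":
        return float((x @ y) / (x @ x))
    r = y / x
    if method == "lad":
        return weighted_median(r, x)
    if method == "log":
        return float(np.exp(sps.trim_mean(np.log(r), trim)))
    raise ValueError(f"unknown slope method {method!r}")


def spike_slope_factors(
    counts: pd.DataFrame,
    spike_genes: Iterable[str],
    reference: str,
    method: str = "log",
    trim: float = 0.1,
) -> SpikeNormFactors:
    """Per-sample scale factors setting the spike-gene slope to 1.

    For every sample a through-origin fit of its spike counts against the
    reference sample's gives the slope; the scale factor is 1/slope (the
    reference's factor is exactly 1). At least 5 spike genes with non-zero
    counts in the reference are required; a non-positive slope raises.
    """
    spikes = [g for g in spike_genes if g in counts.index]
    ref = counts.loc[spikes, reference].to_numpy(dtype=float)
    usable = ref > 0
    if int(usable.sum()) < MIN_SPIKE_GENES:
        raise NormalizationError(
            f"need >= {MIN_SPIKE_GENES} spike genes with non-zero reference counts, "
            f"got {int(usable.sum())}"
        )
    factors = {}
    diag = []
    for sample in counts.columns:
        y = counts.loc[spikes, sample].to_numpy(dtype=float)
        keep = usable & (y > 0)
        if int(keep.sum()) < MIN_SPIKE_GENES:
            raise NormalizationError(
                f"sample {sample!r}: fewer than {MIN_SPIKE_GENES} usable spike genes"
            )
        slope = _slope(ref[keep], y[keep], method, trim)
        if not np.isfinite(slope) or slope <= 0:
            raise NormalizationError(f"sample {sample!r}: non-positive spike slope")
        factors[sample] = 1.0 if sample == reference else 1.0 / slope
        log_resid = np.log(y[keep] / ref[keep]) - np.log(slope)
        diag.append((sample, slope, int(keep.sum()), float(np.median(np.abs(log_resid)))))
    return SpikeNormFactors(
        factors=pd.Series(factors, name="scale_factor"),
        reference=reference,
        diagnostics=pd.DataFrame(
            diag, columns=["sample", "slope", "n_spikes", "residual_spread"]
        ),
    )


def apply_factors(
    counts: pd.DataFrame,
    factors: SpikeNormFactors | pd.Series,
    drop_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Multiply each sample's counts by its scale factor."""
    f = factors.factors if isinstance(factors, SpikeNormFactors) else factors
    out = counts.mul(f, axis=1)
    if drop_genes is not None:
        out = out.drop(index=[g for g in drop_genes if g in out.index])
    return out


def builtin_contrast_test(
    normalized: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    euploid_strain: str = "euploid",
    baseline_timepoint: str = "log",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-sample tests for the silencing contrasts.

    Produces, on log2(normalized + pseudocount) values, one row per gene for
    (a) each quiescent timepoint vs euploid log phase within the euploid
    (``euploid_repression``) and (b) each aneuploid strain vs the euploid at
    each quiescent timepoint (``aneuploid_vs_euploid``), BH-corrected across
    genes within each contrast. This is a stand-in engine with a moderated
    pooled variance; externally computed per-gene statistics in the same
    format are accepted by :func:`call_silencing_defect`.
    """
    log = np.log2(normalized + pseudocount)
    sheet = sample_sheet.set_index("sample")

    def _cols(strain, tp):
        return sheet[(sheet["strain"] == strain) & (sheet["timepoint"] == tp)].index

    strains = [s for s in sheet["strain"].unique() if s != euploid_strain]
    timepoints = [t for t in sheet["timepoint"].unique() if t != baseline_timepoint]
    rows = []
    base = log[_cols(euploid_strain, baseline_timepoint)].to_numpy()
    for tp in timepoints:
        eu = log[_cols(euploid_strain, tp)].to_numpy()
        delta, p = moderated_two_sample(eu, base)
        fdr = bh_adjust(p)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": normalized.index,
                    "kind": EUPLOID_REPRESSION,
                    "strain": euploid_strain,
                    "timepoint": tp,
                    "log2fc": delta,
                    "p_value": p,
                    "fdr": fdr,
                }
            )
        )
        for strain in strains:
            an = log[_cols(strain, tp)].to_numpy()
            delta, p = moderated_two_sample(an, eu)
            fdr = bh_adjust(p)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": normalized.index,
                        "kind": ANEUPLOID_VS_EUPLOID,
                        "strain": strain,
                        "timepoint": tp,
                        "log2fc": delta,
                        "p_value": p,
                        "fdr": fdr,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def call_silencing_defect(
    stats: pd.DataFrame,
    alpha: float = 0.05,
    aneuploids: Sequence[str] | None = None,
) -> list[str]:
    """Genes repressed in the euploid but high in every aneuploid.

    A gene is selected iff it is significantly repressed in the euploid
    (negative log2fc, fdr < alpha, at some timepoint) AND, for every
    aneuploid strain, there is at least one timepoint with significantly
    positive log2fc versus the euploid. A missing aneuploid contrast raises
    naming the strain.
    """
    missing = [c for c in STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"stats table missing columns: {missing}")
    aneu_stats = stats[stats["kind"] == ANEUPLOID_VS_EUPLOID]
    present = set(aneu_stats["strain"].unique())
    if aneuploids is None:
        aneuploids = sorted(present)
        if not aneuploids:
            raise ValueError("no aneuploid_vs_euploid contrasts in stats table")
    else:
        absent = [s for s in aneuploids if s not in present]
        if absent:
            raise ValueError(f"missing aneuploid contrast(s): {absent}")

    rep = stats[stats["kind"] == EUPLOID_REPRESSION]
    repressed = set(
        rep.loc[(rep["fdr"] < alpha) & (rep["log2fc"] < 0), "gene_id"]
    )
    selected = repressed
    for strain in aneuploids:
        sub = aneu_stats[aneu_stats["strain"] == strain]
        higher = set(sub.loc[(sub["fdr"] < alpha) & (sub["log2fc"] > 0), "gene_id"])
        selected = selected & higher
    return sorted(selected)
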