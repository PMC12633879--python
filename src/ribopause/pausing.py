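"""Differential ribosome pausing between euploid and aneuploid samples.

Replicate-paired occupancy traces are compared by uncentered Pearson
correlation; per-codon differences are tested with Fisher's exact test
(codon reads vs gene-body reads, euploid vs aneuploid) with Benjamini-
Hochberg correction across all tested codons within a replicate, and
significant codons are labelled by the direction of the pseudocounted
normalized occupancy ratio. Replicates are combined by union, discarding
direction conflicts. Positional shifts between the two peak directions are
tested with the Wilcoxon rank-sum test, and chromosome enrichment of peak
transcripts with an upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .occupancy import (
    BODY_TRIM,
    OccupancyTrace,
    PSiteCountMatrix,
    body_slice,
    cds_slice,
)
from .stats import bh_adjust, fisher_exact_batch

EUPLOID_HIGHER = "euploid_higher"
ANEUPLOID_HIGHER = "aneuploid_higher"

PEAK_COLUMNS = [
    "gene_id",
    "codon_index",
    "replicate",
    "p_value",
    "fdr",
    "direction",
    "ratio",
    "relative_position",
]


def uncentered_correlation(trace_a, trace_b) -> float:
    """Cosine similarity (uncentered Pearson): sum(ab) / (||a|| ||b||).

    Returns 0.0 for an all-zero vector (degenerate; callers may flag it).
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("traces must have length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def correlate_all(
    traces_e: Mapping[str, OccupancyTrace],
    traces_a: Mapping[str, OccupancyTrace],
    genes: Iterable[str] | None = None,
    replicate: str | int | None = None,
) -> pd.DataFrame:
    """Per-gene uncentered correlation of CDS occupancy, paired by replicate."""
    if genes is None:
        genes = [g for g in traces_e if g in traces_a]
    rows = []
    for g in genes:
        r = uncentered_correlation(traces_e[g].cds, traces_a[g].cds)
        rows.append((g, replicate, r))
    return pd.DataFrame(rows, columns=["gene_id", "replicate", "correlation"])


def codon_fisher_test(
    codon_e: int,
    body_e: int,
    codon_a: int,
    body_a: int,
    exclude_codon: bool = True,
) -> float:
    """Two-sided Fisher exact p for one codon.

    Rows are euploid/aneuploid; columns are reads at the codon vs reads in
    the gene body. With ``exclude_codon`` (default) the body column excludes
    the tested codon so the columns are disjoint; the codon's reads must
    then be contained in the body count.
    """
    if min(codon_e, body_e, codon_a, body_a) < 0:
        raise ValueError("counts must be non-negative")
    rest_e, rest_a = (body_e, body_a)
    if exclude_codon:
        rest_e, rest_a = body_e - codon_e, body_a - codon_a
        if rest_e < 0 or rest_a < 0:
            raise ValueError("codon count exceeds body count")
    return float(fisher_exact_batch(codon_e, rest_e, codon_a, rest_a))


@dataclass
class PeakCallResult:
    peaks: pd.DataFrame  # significant codons only, PEAK_COLUMNS
    n_tested: int
    replicate: str | int | None = None


def call_peaks(
    matrix_e: PSiteCountMatrix,
    matrix_a: PSiteCountMatrix,
    genes: Iterable[str],
    alpha: float = 0.05,
    min_total: int = 0,
    exclude_codon: bool = True,
    pseudocount: float = 1.0,
    replicate: str | int | None = None,
) -> PeakCallResult:
    """Call differentially occupied codons for one replicate pair.

    Every CDS codon of every retained gene whose combined (euploid +
    aneuploid) count is at least ``min_total`` is tested; BH correction runs
    over all tested codons in the replicate. Direction comes from the
    pseudocounted body-normalized occupancy ratio (aneuploid / euploid);
    codons with ratio exactly 1 cannot be given a direction and are never
    reported as peaks.
    """
    gene_arr, codon_arr, ce, ca, rest_e, rest_a, ratio, relpos = (
        [] for _ in range(8)
    )
    for g in genes:
        n = matrix_e.n_codons(g)
        ve = matrix_e.counts[g]
        va = matrix_a.counts[g]
        cds_e = ve[cds_slice(n)]
        cds_a = va[cds_slice(n)]
        body_e = int(ve[body_slice(n)].sum())
        body_a = int(va[body_slice(n)].sum())
        in_body = np.zeros(n, dtype=bool)
        in_body[BODY_TRIM : n - BODY_TRIM] = True
        keep = (cds_e + cds_a) >= min_total
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            continue
        occ_e = (cds_e + pseudocount) / (ve[body_slice(n)] + pseudocount).mean()
        occ_a = (cds_a + pseudocount) / (va[body_slice(n)] + pseudocount).mean()
        gene_arr.append(np.repeat(g, idx.size))
        codon_arr.append(idx + 1)
        ce.append(cds_e[idx])
        ca.append(cds_a[idx])
        if exclude_codon:
            rest_e.append(body_e - cds_e[idx] * in_body[idx])
            rest_a.append(body_a - cds_a[idx] * in_body[idx])
        else:
            rest_e.append(np.full(idx.size, body_e))
            rest_a.append(np.full(idx.size, body_a))
        ratio.append(occ_a[idx] / occ_e[idx])
        relpos.append((idx + 1) / n)
    if not gene_arr:
        return PeakCallResult(
            peaks=pd.DataFrame(columns=PEAK_COLUMNS), n_tested=0, replicate=replicate
        )
    gene_arr = np.concatenate(gene_arr)
    codon_arr = np.concatenate(codon_arr)
    ce, ca = np.concatenate(ce), np.concatenate(ca)
    rest_e, rest_a = np.concatenate(rest_e), np.concatenate(rest_a)
    ratio = np.concatenate(ratio)
    relpos = np.concatenate(relpos)

    p = fisher_exact_batch(ce, rest_e, ca, rest_a)
    fdr = bh_adjust(p)
    sig = (fdr < alpha) & (ratio != 1.0)
    direction = np.where(ratio > 1.0, ANEUPLOID_HIGHER, EUPLOID_HIGHER)
    peaks = pd.DataFrame(
        {
            "gene_id": gene_arr[sig],
            "codon_index": codon_arr[sig],
            "replicate": replicate,
            "p_value": p[sig],
            "fdr": fdr[sig],
            "direction": direction[sig],
            "ratio": ratio[sig],
            "relative_position": relpos[sig],
        }
    )
    # direction labels must always agree with the normalized occupancy ratio
    assert bool(
        np.all((peaks["ratio"] > 1) == (peaks["direction"] == ANEUPLOID_HIGHER))
    )
    return PeakCallResult(peaks=peaks, n_tested=int(p.size), replicate=replicate)


@dataclass
class CombinedPeaks:
    peaks: pd.DataFrame  # gene_id, codon_index, direction, fdr_min, ratio_mean,
    # relative_position, replicates_supporting
    conflicts: pd.DataFrame  # codons discarded for conflicting directions
    summary: pd.DataFrame  # per direction: n_sites, n_transcripts


def combine_replicates(results: Sequence[PeakCallResult]) -> CombinedPeaks:
    """Union of replicate-level significant codons.

    Codons significant in several replicates with conflicting directions are
    discarded and reported separately. The summary counts sites and distinct
    transcripts per direction.
    """
    if not results:
        raise ValueError("need at least one replicate peak set")
    allpeaks = pd.concat([r.peaks for r in results], ignore_index=True)
    if allpeaks.empty:
        empty = pd.DataFrame(
            columns=[
                "gene_id",
                "codon_index",
                "direction",
                "fdr_min",
                "ratio_mean",
                "relative_position",
                "replicates_supporting",
            ]
        )
        summary = pd.DataFrame(
            {"direction": [EUPLOID_HIGHER, ANEUPLOID_HIGHER], "n_sites": 0, "n_transcripts": 0}
        )
        return CombinedPeaks(peaks=empty, conflicts=empty.copy(), summary=summary)
    grouped = allpeaks.groupby(["gene_id", "codon_index"], sort=True)
    agg = grouped.agg(
        n_directions=("direction", "nunique"),
        direction=("direction", "first"),
        fdr_min=("fdr", "min"),
        ratio_mean=("ratio", "mean"),
        relative_position=("relative_position", "first"),
        replicates_supporting=("replicate", "nunique"),
    ).reset_index()
    conflicts = agg[agg["n_directions"] > 1].drop(columns="n_directions")
    peaks = agg[agg["n_directions"] == 1].drop(columns="n_directions")
    summary = (
        peaks.groupby("direction")
        .agg(n_sites=("codon_index", "size"), n_transcripts=("gene_id", "nunique"))
        .reindex([EUPLOID_HIGHER, ANEUPLOID_HIGHER], fill_value=0)
        .reset_index()
    )
    return CombinedPeaks(
        peaks=peaks.reset_index(drop=True),
        conflicts=conflicts.reset_index(drop=True),
        summary=summary,
    )


def peak_position_test(
    positions_a, positions_b, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on relative peak positions.

    Exact enumeration when both groups have at most ``exact_max_n``
    observations and no ties span the groups; otherwise the normal
    approximation with tie correction. Returns (U statistic, p).
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both position sets must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = (
        "exact" if (a.size <= exact_max_n and b.size <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chromosome_enrichment(
    peak_genes: Iterable[str],
    measured_genes: Iterable[str],
    gene_to_chromosome: Mapping[str, str],
    target_chromosome: str,
) -> float:
    """Upper-tail hypergeometric p for target-chromosome transcripts among
    peak transcripts, with all measured transcripts as the background."""
    peak_genes = set(peak_genes)
    measured = set(measured_genes)
    if not peak_genes <= measured:
        raise ValueError("peak transcripts must be a subset of measured transcripts")
    m_total = len(measured)
    k_target = sum(1 for g in measured if gene_to_chromosome[g] == target_chromosome)
    n_draw = len(peak_genes)
    k_obs = sum(1 for g in peak_genes if gene_to_chromosome[g] == target_chromosome)
    return float(sps.hypergeom.sf(k_obs - 1, m_total, k_target, n_draw))
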