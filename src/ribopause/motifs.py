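"""Amino-acid enrichment in the residues flanking differential pause sites.

For every peak the residues at positions -window..+window around the peak
codon are collected (position 0 = P site, +1 = A site; the terminal stop
contributes the stop symbol). Per-position residue frequencies are compared
against proteome background frequencies with two-sided Fisher tests and BH
correction over the whole matrix; enrichment is reported as
log2(observed frequency / background frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import Proteome, SYMBOLS
from .stats import bh_adjust, fisher_exact_batch

DEFAULT_WINDOW = 10


@dataclass
class FlankMatrix:
    """Residue counts at each position relative to the peak codons.

    ``counts`` is a (symbols x positions) table; ``denominators`` gives the
    number of peaks contributing a residue at each position (peaks running
    off a protein end contribute nothing there).
    """

    counts: pd.DataFrame  # index SYMBOLS, columns positions -w..+w
    denominators: pd.Series  # per position
    n_peaks: int

    @property
    def window(self) -> int:
        return int(self.counts.columns.max())


def extract_flanks(
    peaks: pd.DataFrame,
    proteins: Mapping[str, str],
    window: int = DEFAULT_WINDOW,
) -> FlankMatrix:
    """Count residues flanking each peak.

    ``peaks`` needs ``gene_id`` and ``codon_index`` columns (CDS codon,
    1-based; the residue at the peak codon itself is position 0). A peak
    codon beyond its protein's length indicates inconsistent inputs and
    raises.
    """
    positions = np.arange(-window, window + 1)
    counts = pd.DataFrame(
        0, index=pd.Index(SYMBOLS, name="symbol"), columns=positions
    )
    denom = pd.Series(0, index=positions)
    n_peaks = 0
    for row in peaks.itertuples():
        protein = proteins[row.gene_id]
        codon = int(row.codon_index)
        if codon < 1 or codon > len(protein):
            raise ValueError(
                f"peak codon {codon} outside protein of {row.gene_id} "
                f"(length {len(protein)})"
            )
        n_peaks += 1
        for k in positions:
            idx = codon + k  # 1-based residue index
            if 1 <= idx <= len(protein):
                counts.loc[protein[idx - 1], k] += 1
                denom[k] += 1
    return FlankMatrix(counts=counts, denominators=denom, n_peaks=n_peaks)


def position_enrichment(
    flanks: FlankMatrix,
    background: Proteome,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (position, symbol) Fisher enrichment against the proteome.

    Each cell tests (count, denominator - count) against (background
    occurrences, background remainder); BH runs over every cell of the
    matrix at positions with a non-zero denominator. Cells whose observed
    frequency is non-zero on a zero background frequency get infinite
    enrichment (flagged by the value itself); their p is still computed.
    """
    bg_counts = np.array([background.counts[s] for s in SYMBOLS], dtype=np.int64)
    bg_total = int(background.total)
    rows = []
    for pos in flanks.counts.columns:
        d = int(flanks.denominators[pos])
        if d == 0:
            continue
        for si, sym in enumerate(SYMBOLS):
            c = int(flanks.counts.loc[sym, pos])
            rows.append((pos, sym, c, d, bg_counts[si]))
    if not rows:
        return pd.DataFrame(
            columns=[
                "position",
                "symbol",
                "count",
                "denominator",
                "background_freq",
                "log2_enrichment",
                "p_value",
                "fdr",
                "significant",
            ]
        )
    df = pd.DataFrame(rows, columns=["position", "symbol", "count", "denominator", "bg"])
    p = fisher_exact_batch(
        df["count"], df["denominator"] - df["count"], df["bg"], bg_total - df["bg"]
    )
    df["p_value"] = p
    df["fdr"] = bh_adjust(p)
    obs_freq = df["count"] / df["denominator"]
    bg_freq = df["bg"] / bg_total
    with np.errstate(divide="ignore", invalid="ignore"):
        df["log2_enrichment"] = np.log2(obs_freq / bg_freq)
    df["background_freq"] = bg_freq
    df["significant"] = df["fdr"] < alpha
    return df.drop(columns="bg")[
        [
            "position",
            "symbol",
            "count",
            "denominator",
            "background_freq",
            "log2_enrichment",
            "p_value",
            "fdr",
            "significant",
        ]
    ]
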