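"""Scoring helpers: compare caller output against simulation ground truth."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .pausing import ANEUPLOID_HIGHER, EUPLOID_HIGHER


def score_stall_recovery(
    combined_peaks: pd.DataFrame, truth_stalls: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity and direction accuracy of planted stall recovery.

    A planted stall is recovered when its exact (gene, codon) is among the
    combined peak calls; the direction is correct when an aneuploid-affected
    stall is called aneuploid-higher (and vice versa).
    """
    called = {
        (r.gene_id, r.codon_index): r.direction for r in combined_peaks.itertuples()
    }
    expected_direction = {
        "aneuploid": ANEUPLOID_HIGHER,
        "euploid": EUPLOID_HIGHER,
    }
    recovered = 0
    direction_ok = 0
    for row in truth_stalls.itertuples():
        direction = called.get((row.gene_id, row.codon_index))
        if direction is None:
            continue
        recovered += 1
        direction_ok += direction == expected_direction[row.condition]
    n = len(truth_stalls)
    return {
        "n_planted": n,
        "n_recovered": recovered,
        "sensitivity": recovered / n if n else float("nan"),
        "direction_accuracy": direction_ok / recovered if recovered else float("nan"),
    }


def spike_factor_errors(
    recovered: pd.Series, truth: Mapping[str, float]
) -> pd.Series:
    """Relative error of recovered normalization factors.

    The generator's truth factors are data-scale multipliers, so a correct
    normalization factor is their reciprocal: error = |factor * truth - 1|.
    """
    truth = pd.Series(truth)
    return (recovered * truth - 1.0).abs()


def score_screen_hits(
    classified: pd.DataFrame, truth_hits: pd.DataFrame
) -> dict[str, float]:
    truth = truth_hits.set_index("gene_id")["class"]
    found = classified.set_index("gene_id")
    true_found = [g for g in found.index if g in truth.index]
    accuracy = (
        float(np.mean([found.loc[g, "class"] == truth[g] for g in true_found]))
        if true_found
        else float("nan")
    )
    return {
        "n_planted": len(truth),
        "n_hits": len(found),
        "n_true_hits": len(true_found),
        "n_false_hits": len(found) - len(true_found),
        "sensitivity": len(true_found) / len(truth),
        "class_accuracy": accuracy,
    }
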