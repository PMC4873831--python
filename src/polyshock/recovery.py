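"""Score pipeline output against the synthetic generator's planted truth.

Recovery is measured over the genes that enter classification (the
detection filter is a documented pre-filter: a gene expressed below the
detection threshold everywhere has no call to score).  Planted ELD labels
name the matched parent (``eld_parentA``/``eld_parentB``); recovered labels
additionally encode whether that parent was the higher or lower one, so
recovered labels are projected onto the planted vocabulary before
comparison.
"""

from __future__ import annotations

import pandas as pd

from .synthetic_data import GroundTruth
from .transgen import TransgenSummary

__all__ = ["pattern_recovery", "transgen_recovery", "partitioning_recovery"]

_ELD_PROJECTION = {
    "eld_high_parentA": "eld_parentA",
    "eld_low_parentA": "eld_parentA",
    "eld_high_parentB": "eld_parentB",
    "eld_low_parentB": "eld_parentB",
}


def pattern_recovery(calls: pd.DataFrame, truth: GroundTruth) -> tuple[float, int]:
    """Fraction of gene x tissue x generation calls matching the planted label."""
    merged = calls.merge(
        truth.patterns, on=["gene_id", "tissue", "generation"], suffixes=("", "_true")
    )
    if merged.empty:
        raise ValueError("no overlap between calls and planted truth")
    recovered = merged["pattern"].replace(_ELD_PROJECTION)
    return float((recovered == merged["pattern_true"]).mean()), len(merged)


def transgen_recovery(
    summary: TransgenSummary, truth: GroundTruth, calls: pd.DataFrame
) -> dict[str, float]:
    """Set agreement between recovered and planted consistent memberships.

    The planted set is restricted to genes with calls in the summary's
    tissue.  Returns recall, precision and Jaccard agreement.
    """
    called = set(calls.loc[calls["tissue"] == summary.tissue, "gene_id"])
    planted = truth.consistent_gene_set(summary.tissue, summary.generations) & called
    recovered = set(summary.consistent_genes)
    inter = len(planted & recovered)
    union = len(planted | recovered)
    return {
        "recall": inter / len(planted) if planted else float("nan"),
        "precision": inter / len(recovered) if recovered else float("nan"),
        "jaccard": inter / union if union else float("nan"),
        "n_planted": float(len(planted)),
        "n_recovered": float(len(recovered)),
    }


def partitioning_recovery(pcalls: pd.DataFrame, truth: GroundTruth) -> tuple[float, int]:
    """Fraction of comparable data points matching the planted outcome.

    Planted ``unaltered`` corresponds to a recovered ``stable`` call; a
    ``shifted_bias`` call never matches a planted outcome (the generator
    does not plant that configuration).
    """
    if truth.homeolog is None:
        raise ValueError("truth has no homeolog outcomes; run simulate_homeolog first")
    merged = pcalls.merge(
        truth.homeolog[["gene_id", "outcome"]], on="gene_id", suffixes=("", "_true")
    )
    if merged.empty:
        raise ValueError("no overlap between partitioning calls and planted truth")
    planted = merged["outcome_true"].replace({"unaltered": "stable"})
    return float((merged["outcome"] == planted).mean()), len(merged)
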