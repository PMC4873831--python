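"""Transgenerational consistency of nonadditive expression.

A gene is transgenerationally consistent when it shows the same nonadditive
expression pattern in every studied generation (``exact_pattern``, the
default), or merely nonadditive expression of any pattern in every
generation (``nonadditive_only``).  Genes classified ``ambiguous`` in any
generation are excluded: no pattern identity can be asserted for them.

Consistent genes decompose into eight source bins by parental status and
pattern (PEC/PED x over/under-TRE, plus the four PED-only ELD bins), and the
aggregate TRE vs ELD contribution is compared by a two-proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .categorize import TRE_PATTERNS
from .stats import PropTestResult, prop_test

__all__ = ["TransgenSummary", "find_consistent", "decompose_sources", "SOURCE_BINS"]

SOURCE_BINS = (
    "PEC_over_tre",
    "PEC_under_tre",
    "PED_over_tre",
    "PED_under_tre",
    "PED_eld_high_A",
    "PED_eld_high_B",
    "PED_eld_low_A",
    "PED_eld_low_B",
)

_BIN_BY_PATTERN = {
    "eld_high_parentA": "PED_eld_high_A",
    "eld_high_parentB": "PED_eld_high_B",
    "eld_low_parentA": "PED_eld_low_A",
    "eld_low_parentB": "PED_eld_low_B",
}


@dataclass(frozen=True)
class TransgenSummary:
    """Consistent nonadditive gene set for one tissue, with bookkeeping."""

    tissue: str
    match_mode: str
    generations: tuple[str, ...]
    consistent_genes: tuple[str, ...]
    nonadditive_counts: dict[str, int]
    consistent_share: dict[str, float]
    source_breakdown: dict[str, int] | None = None
    tre_vs_eld: PropTestResult | None = None


def find_consistent(
    calls: pd.DataFrame,
    tissue: str,
    generations,
    match_mode: str = "exact_pattern",
) -> TransgenSummary:
    """Identify genes whose nonadditive expression persists across generations.

    ``consistent_share`` is |consistent| / |nonadditive in that generation|.
    Raises if any configured generation has no calls for the tissue.
    """
    if match_mode not in ("exact_pattern", "nonadditive_only"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    generations = tuple(generations)
    sub = calls[calls["tissue"] == tissue]
    have = set(sub["generation"].unique())
    missing = [g for g in generations if g not in have]
    if missing:
        raise ValueError(f"no calls for generation(s) {missing} in tissue {tissue!r}")
    sub = sub[sub["generation"].isin(generations)]

    wide_pat = sub.pivot(index="gene_id", columns="generation", values="pattern")
    wide_add = sub.pivot(index="gene_id", columns="generation", values="additivity")
    complete = wide_pat.notna().all(axis=1)
    nonadd_all = (wide_add == "nonadditive").all(axis=1)
    no_ambiguous = (wide_pat != "ambiguous").all(axis=1)
    if match_mode == "exact_pattern":
        same = wide_pat.nunique(axis=1) == 1
        keep = complete & nonadd_all & no_ambiguous & same
    else:
        keep = complete & nonadd_all & no_ambiguous
    consistent = tuple(sorted(wide_pat.index[keep]))

    nonadd_counts = {
        gen: int((sub[sub["generation"] == gen]["additivity"] == "nonadditive").sum())
        for gen in generations
    }
    share = {
        gen: (len(consistent) / n if n else float("nan"))
        for gen, n in nonadd_counts.items()
    }
    return TransgenSummary(
        tissue=tissue,
        match_mode=match_mode,
        generations=generations,
        consistent_genes=consistent,
        nonadditive_counts=nonadd_counts,
        consistent_share=share,
    )


def decompose_sources(summary: TransgenSummary, calls: pd.DataFrame) -> TransgenSummary:
    """Assign each consistent gene to one source bin; test TRE vs ELD.

    Requires a summary computed under ``exact_pattern`` (a single pattern
    label per gene is needed to bin it).  The TRE-vs-ELD comparison is a
    two-proportion test of (n_TRE, n_consistent) vs (n_ELD, n_consistent).
    """
    if summary.match_mode != "exact_pattern":
        raise ValueError("source decomposition requires match_mode='exact_pattern'")
    gen0 = summary.generations[0]
    sub = calls[
        (calls["tissue"] == summary.tissue)
        & (calls["generation"] == gen0)
        & calls["gene_id"].isin(summary.consistent_genes)
    ].set_index("gene_id")

    breakdown = {b: 0 for b in SOURCE_BINS}
    for gene in summary.consistent_genes:
        pattern = sub.loc[gene, "pattern"]
        status = sub.loc[gene, "parental_status"]
        if pattern in TRE_PATTERNS:
            bin_name = f"{status}_{pattern}"
        else:
            bin_name = _BIN_BY_PATTERN[pattern]
        breakdown[bin_name] += 1

    n = len(summary.consistent_genes)
    n_tre = sum(v for k, v in breakdown.items() if k.endswith("_tre"))
    n_eld = sum(v for k, v in breakdown.items() if "_eld_" in k)
    test = prop_test(n_tre, n, n_eld, n) if n else None
    return replace(summary, source_breakdown=breakdown, tre_vs_eld=test)


def summary_frame(summary: TransgenSummary) -> pd.DataFrame:
    """Long-format (section, key, value) table of a TransgenSummary."""
    rows = [
        ("meta", "tissue", summary.tissue),
        ("meta", "match_mode", summary.match_mode),
        ("consistent", "n_consistent", len(summary.consistent_genes)),
    ]
    for gen in summary.generations:
        rows.append(("nonadditive_count", gen, summary.nonadditive_counts[gen]))
        rows.append(("consistent_share", gen, round(summary.consistent_share[gen], 6)))
    if summary.source_breakdown is not None:
        for b in SOURCE_BINS:
            rows.append(("source", b, summary.source_breakdown[b]))
    if summary.tre_vs_eld is not None:
        rows.append(("tre_vs_eld", "chi_sq", round(summary.tre_vs_eld.chi_sq, 6)))
        rows.append(("tre_vs_eld", "p_value", round(summary.tre_vs_eld.p_value, 6)))
    return pd.DataFrame(rows, columns=["section", "key", "value"])
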