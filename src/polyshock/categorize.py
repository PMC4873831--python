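"""Core classification: detection filtering, PEC/PED, additivity, ELD/TRE.

The expression space is constrained: a gene whose parents do not differ
(PEC) can only be constant or transgressive in the polyploid, while a gene
with diverged parents (PED) can additionally show expression-level dominance
(ELD) toward either parent.  "Equal expression" is operationalized as
non-significance of the corresponding moderated-t contrast at the configured
FDR threshold — the convention of this analysis style, accepted here as
absence-of-evidence.

Per gene and generation three Benjamini-Yekutieli-adjusted moderated-t
contrasts are computed: polyploid vs the mid-parent group (T_m), vs parent A
(T_a) and vs parent B (T_b).  The decision tree:

1. T_m not significant -> additive (pattern ``constant`` for PEC,
   ``additive`` for PED).
2. T_m significant -> nonadditive:
   above both parents -> ``over_tre``; below both -> ``under_tre``;
   for PED genes, indistinguishable from the higher parent while different
   from the lower -> ``eld_high_<parent>`` (and symmetrically
   ``eld_low_<parent>``); anything else -> ``ambiguous``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iolayer import CATEGORY_CALL_COLUMNS, ExpressionDataset
from .stats import moderated_t_matrix, prop_test

logger = logging.getLogger("polyshock.categorize")

__all__ = [
    "detection_filter",
    "compute_mpv",
    "classify_parental",
    "classify_pattern",
    "classify_tissue",
    "summarize_categories",
    "MpvResult",
    "CategorySummary",
]

ELD_PATTERNS = (
    "eld_high_parentA",
    "eld_high_parentB",
    "eld_low_parentA",
    "eld_low_parentB",
)
TRE_PATTERNS = ("over_tre", "under_tre")
NONADDITIVE_PATTERNS = TRE_PATTERNS + ELD_PATTERNS + ("ambiguous",)
ALL_PATTERNS = ("constant", "additive") + NONADDITIVE_PATTERNS


def detection_filter(
    dataset: ExpressionDataset, threshold: float = 5.0, tissue: str | None = None
) -> tuple[pd.DataFrame, ExpressionDataset]:
    """Reproducibility filter: keep genes reliably detected somewhere.

    A gene is "present" in a genotype group (tissue x role x generation) iff
    every replicate is at or above ``threshold`` (log2 scale); a gene is
    retained iff present in at least one group.  With ``tissue`` given, the
    dataset is first restricted to that tissue's samples.  Returns the
    per-group presence flags and the filtered dataset.
    """
    if tissue is not None:
        dataset = dataset.subset_samples(dataset.sample_ids(tissue=tissue))
    man = dataset.manifest
    flags = {}
    for (tis, role, gen), grp in man.groupby(["tissue", "role", "generation"], sort=True):
        label = f"{tis}:{role}:{gen}" if gen else f"{tis}:{role}"
        flags[label] = (dataset.matrix(list(grp.index)) >= threshold).all(axis=1)
    flag_df = pd.DataFrame(flags, index=dataset.values.index)
    keep = flag_df.any(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "detection filter (threshold=%.3g): removed %d of %d genes",
            threshold,
            n_removed,
            len(keep),
        )
    return flag_df, dataset.subset_genes(flag_df.index[keep])


@dataclass
class MpvResult:
    """Mid-parent value group: per-gene MPV and its replicate matrix."""

    values: pd.Series
    replicates: np.ndarray
    labels: list[str]
    mode: str


def compute_mpv(
    dataset: ExpressionDataset, tissue: str, mode: str = "measured_mix"
) -> MpvResult:
    """Build the mid-parent reference group for a tissue.

    ``measured_mix`` uses the 1:1 parental RNA-pool samples as the MPV
    group; ``computed`` forms per-replicate MPVs on the linear scale,
    MPV_i = log2((2^a_i + 2^b_i) / 2), pairing parental replicates by index
    (down to the smaller replicate count, with a warning if unequal).
    """
    if mode == "measured_mix":
        ids = dataset.sample_ids(role="mix", tissue=tissue)
        if len(ids) < 2:
            raise ValueError(
                f"mpv_mode='measured_mix' requires >=2 mix samples in tissue {tissue!r}"
            )
        mat = dataset.matrix(ids)
        return MpvResult(
            values=pd.Series(mat.mean(axis=1), index=dataset.values.index),
            replicates=mat,
            labels=ids,
            mode=mode,
        )
    if mode == "computed":
        a_ids = dataset.sample_ids(role="parentA", tissue=tissue)
        b_ids = dataset.sample_ids(role="parentB", tissue=tissue)
        if len(a_ids) < 2 or len(b_ids) < 2:
            raise ValueError(f"computed MPV requires >=2 replicates per parent in {tissue!r}")
        k = min(len(a_ids), len(b_ids))
        if len(a_ids) != len(b_ids):
            logger.warning(
                "unequal parental replicate counts (%d vs %d); pairing first %d",
                len(a_ids),
                len(b_ids),
                k,
            )
        a = dataset.matrix(a_ids[:k])
        b = dataset.matrix(b_ids[:k])
        mat = np.log2((2.0**a + 2.0**b) / 2.0)
        return MpvResult(
            values=pd.Series(mat.mean(axis=1), index=dataset.values.index),
            replicates=mat,
            labels=[f"mpv_r{i + 1}" for i in range(k)],
            mode=mode,
        )
    raise ValueError(f"unknown MPV mode {mode!r}; expected 'measured_mix' or 'computed'")


def classify_parental(
    dataset: ExpressionDataset,
    tissue: str,
    alpha: float = 0.05,
    *,
    ordinary: bool = False,
) -> pd.DataFrame:
    """PEC/PED assignment: moderated t between the parents, BY-adjusted.

    A gene is PED iff the adjusted p-value is below ``alpha``; its direction
    is the sign of the parent A minus parent B log2 fold change.
    """
    a_ids = dataset.sample_ids(role="parentA", tissue=tissue)
    b_ids = dataset.sample_ids(role="parentB", tissue=tissue)
    res = moderated_t_matrix(
        dataset.matrix(a_ids), dataset.matrix(b_ids), dataset.gene_ids, ordinary=ordinary
    )
    ped = res["p_adjusted"].to_numpy() < alpha
    res["parental_status"] = np.where(ped, "PED", "PEC")
    res["ped_direction"] = np.where(
        ped, np.where(res["log_fc"] > 0, "A_higher", "B_higher"), "none"
    )
    return res[["gene_id", "parental_status", "ped_direction", "log_fc", "p_adjusted"]]


def classify_pattern(
    dataset: ExpressionDataset,
    tissue: str,
    generation: str,
    parental: pd.DataFrame,
    alpha: float = 0.05,
    mpv_mode: str = "measured_mix",
    *,
    ordinary: bool = False,
) -> pd.DataFrame:
    """Additivity and ELD/TRE pattern calls for one tissue x generation."""
    poly_ids = dataset.sample_ids(role="polyploid", tissue=tissue, generation=generation)
    if not poly_ids:
        raise ValueError(f"no polyploid samples for tissue {tissue!r}, generation {generation!r}")
    poly = dataset.matrix(poly_ids)
    mpv = compute_mpv(dataset, tissue, mpv_mode)
    a = dataset.matrix(dataset.sample_ids(role="parentA", tissue=tissue))
    b = dataset.matrix(dataset.sample_ids(role="parentB", tissue=tissue))
    genes = dataset.gene_ids

    t_m = moderated_t_matrix(poly, mpv.replicates, genes, ordinary=ordinary)
    t_a = moderated_t_matrix(poly, a, genes, ordinary=ordinary)
    t_b = moderated_t_matrix(poly, b, genes, ordinary=ordinary)

    par = parental.set_index("gene_id").loc[genes]
    status = par["parental_status"].to_numpy()
    a_higher = par["ped_direction"].to_numpy() == "A_higher"
    is_ped = status == "PED"

    sig_m = t_m["p_adjusted"].to_numpy() < alpha
    sig_a = t_a["p_adjusted"].to_numpy() < alpha
    sig_b = t_b["p_adjusted"].to_numpy() < alpha
    fc_a = t_a["log_fc"].to_numpy()
    fc_b = t_b["log_fc"].to_numpy()

    over = sig_m & sig_a & sig_b & (fc_a > 0) & (fc_b > 0)
    under = sig_m & sig_a & sig_b & (fc_a < 0) & (fc_b < 0)
    match_a_only = ~sig_a & sig_b  # polyploid ~ parent A, differs from B
    match_b_only = ~sig_b & sig_a

    conditions = [
        ~sig_m & (status == "PEC"),
        ~sig_m,
        over,
        under,
        is_ped & a_higher & match_a_only,
        is_ped & a_higher & match_b_only,
        is_ped & ~a_higher & match_b_only,
        is_ped & ~a_higher & match_a_only,
    ]
    choices = [
        "constant",
        "additive",
        "over_tre",
        "under_tre",
        "eld_high_parentA",
        "eld_low_parentB",
        "eld_high_parentB",
        "eld_low_parentA",
    ]
    pattern = np.select(conditions, choices, default="ambiguous")

    calls = pd.DataFrame(
        {
            "gene_id": genes,
            "tissue": tissue,
            "generation": generation,
            "parental_status": status,
            "ped_direction": par["ped_direction"].to_numpy(),
            "additivity": np.where(sig_m, "nonadditive", "additive"),
            "pattern": pattern,
            "mpv": mpv.values.to_numpy(),
        },
        columns=list(CATEGORY_CALL_COLUMNS),
    )
    return calls


def classify_tissue(
    dataset: ExpressionDataset,
    tissue: str,
    generations,
    alpha: float = 0.05,
    mpv_mode: str = "measured_mix",
    detection_threshold: float = 5.0,
    *,
    ordinary: bool = False,
) -> pd.DataFrame:
    """Filter + classify every configured generation of one tissue."""
    _, filtered = detection_filter(dataset, detection_threshold, tissue=tissue)
    parental = classify_parental(filtered, tissue, alpha, ordinary=ordinary)
    frames = [
        classify_pattern(
            filtered, tissue, gen, parental, alpha, mpv_mode, ordinary=ordinary
        )
        for gen in generations
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class CategorySummary:
    """Counts/proportions per stratum plus PEC-vs-PED propensity tests."""

    pattern_counts: pd.DataFrame
    propensity: pd.DataFrame
    tissue_comparison: pd.DataFrame | None = None


def summarize_categories(calls: pd.DataFrame) -> CategorySummary:
    """Tabulate pattern frequencies and PEC/PED x additivity propensities.

    ``propensity`` tests, per tissue x generation, whether PEC and PED genes
    have equal probabilities of nonadditive expression (two-proportion
    test); ``tissue_comparison`` compares nonadditive shares between tissue
    pairs within each generation when more than one tissue is present.
    """
    counts = (
        calls.groupby(["tissue", "generation", "pattern"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["tissue", "generation"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals

    rows = []
    for (tis, gen), grp in calls.groupby(["tissue", "generation"], sort=True):
        pec = grp[grp["parental_status"] == "PEC"]
        ped = grp[grp["parental_status"] == "PED"]
        n_pec, n_ped = len(pec), len(ped)
        na_pec = int((pec["additivity"] == "nonadditive").sum())
        na_ped = int((ped["additivity"] == "nonadditive").sum())
        if n_pec and n_ped:
            test = prop_test(na_pec, n_pec, na_ped, n_ped)
            chi, p = test.chi_sq, test.p_value
        else:
            chi, p = np.nan, np.nan
        rows.append(
            {
                "tissue": tis,
                "generation": gen,
                "n_pec": n_pec,
                "nonadd_pec": na_pec,
                "n_ped": n_ped,
                "nonadd_ped": na_ped,
                "prop_nonadd_pec": na_pec / n_pec if n_pec else np.nan,
                "prop_nonadd_ped": na_ped / n_ped if n_ped else np.nan,
                "chi_sq": chi,
                "p_value": p,
            }
        )
    propensity = pd.DataFrame(rows)

    tissues = sorted(calls["tissue"].unique())
    comparison = None
    if len(tissues) >= 2:
        comp_rows = []
        for gen, grp in calls.groupby("generation", sort=True):
            for i in range(len(tissues)):
                for j in range(i + 1, len(tissues)):
                    g1 = grp[grp["tissue"] == tissues[i]]
                    g2 = grp[grp["tissue"] == tissues[j]]
                    if g1.empty or g2.empty:
                        continue
                    x1 = int((g1["additivity"] == "nonadditive").sum())
                    x2 = int((g2["additivity"] == "nonadditive").sum())
                    test = prop_test(x1, len(g1), x2, len(g2))
                    comp_rows.append(
                        {
                            "generation": gen,
                            "tissue1": tissues[i],
                            "tissue2": tissues[j],
                            "nonadd1": x1,
                            "n1": len(g1),
                            "nonadd2": x2,
                            "n2": len(g2),
                            "chi_sq": test.chi_sq,
                            "p_value": test.p_value,
                        }
                    )
        comparison = pd.DataFrame(comp_rows)
    return CategorySummary(counts, propensity, comparison)
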