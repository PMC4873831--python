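"""Homeolog expression partitioning and subgenome dominance.

For each comparable data point — a gene x generation with (a) a
total-expression category call and (b) at least two replicate A-subgenome
allele fractions in both the polyploid generation and the parental 1:1 mix —
partitioning is *altered* when a two-sample t-test of the polyploid vs the
mix fractions is significant (raw p < alpha, Welch by default).  Bias of
either group is a one-sample t-test of the fractions against 0.5.  Altered
points classify qualitatively as

* ``erasure``    — mix biased, polyploid not (a parental ortholog bias
  returning to 50:50);
* ``novel_bias`` — mix unbiased, polyploid biased (a new bias arising);
* ``shifted_bias`` — any other altered configuration (bias retained in the
  same direction, or reversed); unaltered points are ``stable``.

``summarize_dominance`` aggregates per-genotype mean A-fractions and bias
counts, and tests each genotype's shift against the mix baseline with a
paired t-test on per-gene mean fractions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iolayer import PARTITIONING_CALL_COLUMNS, HomeologTable
from .stats import one_sample_t, prop_test, two_sample_t
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("polyshock.homeolog")

__all__ = [
    "call_partitioning",
    "tabulate_comparable",
    "compare_tissues",
    "summarize_dominance",
]

OUTCOMES = ("stable", "erasure", "novel_bias", "shifted_bias")


def _annotate(homeolog: HomeologTable, manifest: pd.DataFrame) -> pd.DataFrame:
    frame = homeolog.frame
    unknown = sorted(set(frame["sample_id"]) - set(manifest.index))
    if unknown:
        raise ValueError(f"homeolog samples missing from manifest: {unknown[:10]}")
    meta = manifest[["role", "tissue", "generation"]]
    return frame.join(meta, on="sample_id")


def _bias_call(values: np.ndarray, alpha: float) -> tuple[bool, float]:
    t, p = one_sample_t(values, 0.5)
    return p < alpha, p


def call_partitioning(
    homeolog: HomeologTable,
    manifest: pd.DataFrame,
    calls: pd.DataFrame,
    tissue: str,
    alpha: float = 0.05,
    *,
    pooled: bool = False,
    adjust_bias: bool = False,
) -> pd.DataFrame:
    """Altered/stable + qualitative outcome per comparable data point.

    Genes present in the homeolog table but absent from the category calls
    are skipped (not comparable) and logged.  With ``adjust_bias=True`` the
    per-group bias p-values are Benjamini-Hochberg adjusted across genes
    within each generation before thresholding.
    """
    ann = _annotate(homeolog, manifest)
    ann = ann[ann["tissue"] == tissue]
    tissue_calls = calls[calls["tissue"] == tissue]
    call_idx = tissue_calls.set_index(["gene_id", "generation"])

    mix = ann[ann["role"] == "mix"]
    mix_by_gene = {g: grp["a_fraction"].to_numpy() for g, grp in mix.groupby("gene_id")}
    poly = ann[ann["role"] == "polyploid"]

    skipped: set[str] = set()
    rows = []
    for (gene, gen), grp in poly.groupby(["gene_id", "generation"], sort=True):
        if (gene, gen) not in call_idx.index:
            skipped.add(gene)
            continue
        poly_f = grp["a_fraction"].to_numpy()
        mix_f = mix_by_gene.get(gene, np.empty(0))
        if poly_f.size < 2 or mix_f.size < 2:
            skipped.add(gene)
            continue
        _, p_alt = two_sample_t(poly_f, mix_f, pooled=pooled)
        mix_biased, p_mix = _bias_call(mix_f, alpha)
        poly_biased, p_poly = _bias_call(poly_f, alpha)
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "generation": gen,
                "expression_class": call_idx.loc[(gene, gen), "additivity"],
                "p_altered": p_alt,
                "p_mix_bias": p_mix,
                "p_poly_bias": p_poly,
                "mix_mean_fraction": float(mix_f.mean()),
                "poly_mean_fraction": float(poly_f.mean()),
            }
        )
    if skipped:
        logger.info(
            "skipped %d homeolog gene(s) without a matching category call or "
            "sufficient replicates: %s%s",
            len(skipped),
            sorted(skipped)[:10],
            " ..." if len(skipped) > 10 else "",
        )
    if not rows:
        return pd.DataFrame(columns=list(PARTITIONING_CALL_COLUMNS))

    out = pd.DataFrame(rows)
    if adjust_bias:
        for col in ("p_mix_bias", "p_poly_bias"):
            out[col] = out.groupby("generation")[col].transform(
                lambda p: multipletests(p, method="fdr_bh")[1]
            )
    out["altered"] = out["p_altered"] < alpha
    out["mix_biased"] = out["p_mix_bias"] < alpha
    out["poly_biased"] = out["p_poly_bias"] < alpha

    conditions = [
        ~out["altered"],
        out["altered"] & out["mix_biased"] & ~out["poly_biased"],
        out["altered"] & ~out["mix_biased"] & out["poly_biased"],
    ]
    out["outcome"] = np.select(conditions, ["stable", "erasure", "novel_bias"], "shifted_bias")
    return out[list(PARTITIONING_CALL_COLUMNS)]


def tabulate_comparable(
    pcalls: pd.DataFrame, expression_class: str
) -> tuple[int, int, float | None]:
    """(n_altered, n_total, proportion) over one expression class.

    ``proportion`` is ``None`` when no data point has the requested class.
    """
    if expression_class not in ("additive", "nonadditive"):
        raise ValueError(f"unknown expression class {expression_class!r}")
    sub = pcalls[pcalls["expression_class"] == expression_class]
    n_total = len(sub)
    n_altered = int(sub["altered"].sum())
    proportion = n_altered / n_total if n_total else None
    return n_altered, n_total, proportion


def compare_tissues(
    pcalls1: pd.DataFrame, pcalls2: pd.DataFrame, expression_class: str
):
    """Two-proportion test of altered shares between two tissues' calls."""
    x1, n1, _ = tabulate_comparable(pcalls1, expression_class)
    x2, n2, _ = tabulate_comparable(pcalls2, expression_class)
    return prop_test(x1, n1, x2, n2)


def summarize_dominance(
    homeolog: HomeologTable,
    manifest: pd.DataFrame,
    genotypes=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-genotype subgenome dominance summary.

    A genotype is a polyploid generation or a natural accession (its
    ``generation`` field); the mix is the baseline.  Per genotype: the mean
    of per-gene mean A-fractions, counts of A-biased / B-biased / unbiased
    genes (one-sample t vs 0.5 on replicates), and a paired t-test of the
    per-gene means against the mix, paired by gene.  Genotypes without data
    are omitted with a warning.
    """
    ann = _annotate(homeolog, manifest)

    def genotype_label(row) -> str | None:
        if row.role == "mix":
            return "mix"
        if row.role in ("polyploid", "natural"):
            return row.generation
        return None

    ann = ann.assign(genotype=[genotype_label(r) for r in ann.itertuples()])
    ann = ann[ann["genotype"].notna()]
    order = ["mix"] + [
        g for g in dict.fromkeys(ann["genotype"]) if g != "mix"
    ]
    if genotypes is not None:
        requested = ["mix"] + [g for g in genotypes if g != "mix"]
        missing = [g for g in requested if g not in set(ann["genotype"])]
        for g in missing:
            logger.warning("genotype %r has no homeolog data; omitted", g)
        order = [g for g in requested if g not in missing]

    mix_means = (
        ann[ann["genotype"] == "mix"].groupby("gene_id")["a_fraction"].mean()
        if "mix" in order
        else pd.Series(dtype=float)
    )

    rows = []
    for geno in order:
        sub = ann[ann["genotype"] == geno]
        gene_means = sub.groupby("gene_id")["a_fraction"].mean()
        n_a = n_b = n_un = 0
        for gene, grp in sub.groupby("gene_id"):
            vals = grp["a_fraction"].to_numpy()
            if vals.size < 2:
                n_un += 1
                continue
            t, p = one_sample_t(vals, 0.5)
            if p < alpha and t > 0:
                n_a += 1
            elif p < alpha and t < 0:
                n_b += 1
            else:
                n_un += 1
        shift = np.nan
        p_shift = np.nan
        if geno != "mix" and len(mix_means):
            common = gene_means.index.intersection(mix_means.index)
            if len(common) >= 1:
                d = (gene_means.loc[common] - mix_means.loc[common]).to_numpy()
                shift = float(d.mean())
                if len(common) >= 2:
                    if np.ptp(d) == 0:
                        p_shift = 1.0 if shift == 0 else 0.0
                    else:
                        p_shift = float(sps.ttest_rel(
                            gene_means.loc[common], mix_means.loc[common]
                        ).pvalue)
        rows.append(
            {
                "genotype": geno,
                "n_genes": int(gene_means.size),
                "mean_a_fraction": float(gene_means.mean()),
                "n_a_biased": n_a,
                "n_b_biased": n_b,
                "n_unbiased": n_un,
                "shift_vs_mix": shift,
                "p_shift": p_shift,
            }
        )
    return pd.DataFrame(rows)
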