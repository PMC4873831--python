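"""Statistical primitives shared by every pipeline stage.

The central primitive is the empirical-Bayes moderated t-statistic: per-gene
pooled residual variances are "squeezed" toward a prior variance ``s0_sq``
estimated across all genes, which stabilizes denominators at small replicate
numbers.  The hierarchical model is the standard one for microarray-style
differential expression: gene-wise variances s2_g are scaled chi-square about
a prior with ``d0`` degrees of freedom, so the posterior variance is

    s2_tilde_g = (d0 * s0_sq + df * s2_g) / (d0 + df)

and the moderated t is referred to a t distribution on ``d0 + df`` degrees of
freedom.  The hyperparameters are fitted by moment matching on log variances.

Multiple-testing adjustment uses the Benjamini-Yekutieli step-up (valid under
arbitrary dependence; includes the c(m) = sum 1/k factor), and categorical
comparisons use the continuity-corrected chi-square two-proportion test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("polyshock.stats")

__all__ = [
    "ModeratedTParams",
    "PropTestResult",
    "fit_variance_prior",
    "moderated_t",
    "moderated_t_matrix",
    "adjust_by",
    "prop_test",
    "one_sample_t",
    "two_sample_t",
]


@dataclass(frozen=True)
class ModeratedTParams:
    """Empirical-Bayes hyperparameters of the variance prior.

    d0 : prior degrees of freedom (0 = no moderation, inf = fully shared
         variance); s0_sq : prior (squeezed-toward) variance.
    """

    d0: float
    s0_sq: float


@dataclass(frozen=True)
class PropTestResult:
    """Continuity-corrected chi-square two-proportion test result."""

    chi_sq: float
    p_value: float

    def __iter__(self):
        return iter((self.chi_sq, self.p_value))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> ModeratedTParams | None:
    """Moment-match the scaled-inverse-chi-square variance prior.

    Works on e_g = log(s2_g) - digamma(df/2) + log(df/2), whose mean and
    excess variance over trigamma(df/2) identify s0_sq and d0.  Genes with
    zero residual variance are excluded from the fit.  Returns ``None`` when
    fewer than two positive variances are available (estimation impossible).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return None
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # Fully shared variance: the plain mean of the gene-wise variances
        # is the natural scale estimate in this limit.
        d0 = np.inf
        s0_sq = float(s2[np.isfinite(s2) & (s2 >= 0)].mean())
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def _group_matrix(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a genes x replicates matrix")
    if x.shape[1] < 2:
        raise ValueError(
            f"{name} has {x.shape[1]} replicate(s); >=2 are required for a contrast"
        )
    return x


def moderated_t_matrix(
    x1,
    x2,
    gene_ids=None,
    *,
    params: ModeratedTParams | None = None,
    ordinary: bool = False,
) -> pd.DataFrame:
    """Moderated t contrast between two replicate matrices (genes x reps).

    ``log_fc`` is mean(x1) - mean(x2) on the log2 scale of the input.  With
    ``ordinary=True`` (or ``params=ModeratedTParams(0, 0)``) this is exactly
    the classical pooled-variance two-sample t-test.  Zero-variance limits
    are defined: identical means give t=0, p=1; separated means with zero
    pooled variance give t=+/-inf, p=0.

    Returns a DataFrame with columns gene_id, log_fc, t_stat, p_value,
    p_adjusted (Benjamini-Yekutieli across the supplied genes) and df_total;
    the fitted hyperparameters are stored in ``result.attrs["params"]``.
    """
    x1 = _group_matrix(x1, "group1")
    x2 = _group_matrix(x2, "group2")
    if x1.shape[0] != x2.shape[0]:
        raise ValueError("group matrices disagree on gene count")
    n_genes = x1.shape[0]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    diff = m1 - m2
    df = float(n1 + n2 - 2)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if ordinary:
        params = ModeratedTParams(0.0, 0.0)
    if params is None:
        params = fit_variance_prior(s2, df)
        if params is None:
            logger.warning(
                "gene-wise residual variances are degenerate (all zero); "
                "falling back to the ordinary t-test"
            )
            params = ModeratedTParams(0.0, 0.0)

    d0, s0_sq = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_post = np.full(n_genes, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(n_genes)
    nz = se > 0
    t[nz] = diff[nz] / se[nz]
    degenerate = ~nz & (diff != 0)
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p = 2.0 * sps.t.sf(np.abs(t), df_total)

    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    out = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log_fc": diff,
            "t_stat": t,
            "p_value": p,
            "p_adjusted": adjust_by(p),
            "df_total": np.full(n_genes, df_total),
        }
    )
    out.attrs["params"] = params
    return out


def moderated_t(
    dataset,
    group1_samples,
    group2_samples,
    *,
    params: ModeratedTParams | None = None,
    ordinary: bool = False,
) -> pd.DataFrame:
    """Moderated t contrast between two disjoint sample groups of a dataset."""
    g1 = list(group1_samples)
    g2 = list(group2_samples)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"contrast groups overlap: {sorted(overlap)}")
    x1 = dataset.matrix(g1)
    x2 = dataset.matrix(g2)
    return moderated_t_matrix(
        x1, x2, dataset.gene_ids, params=params, ordinary=ordinary
    )


def adjust_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (FDR under dependence).

    q_i = min_{j>=i} (m * c(m) / j) * p_(j), capped at 1, with
    c(m) = sum_{k=1..m} 1/k; the original input order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def prop_test(x1: int, n1: int, x2: int, n2: int, *, correction: bool = True) -> PropTestResult:
    """Two-sample proportion test as a chi-square on the 2x2 table.

    Applies the Yates continuity correction by default (the convention of
    R's ``prop.test``), 1 degree of freedom.  Degenerate tables (all
    successes or all failures) have chi_sq=0, p=1 by definition.
    """
    for x, n, lab in ((x1, n1, "1"), (x2, n2, "2")):
        if n < 1:
            raise ValueError(f"sample {lab}: n must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"sample {lab}: need 0 <= x <= n, got x={x}, n={n}")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:
        return PropTestResult(0.0, 1.0)
    res = sps.chi2_contingency(table, correction=correction)
    return PropTestResult(float(res[0]), float(res[1]))


def one_sample_t(values, mu0: float) -> tuple[float, float]:
    """Classical one-sample t-test of mean(values) == mu0.

    Zero-variance data are a defined limit: t=0, p=1 when the common value
    equals mu0, else t=+/-inf, p=0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one_sample_t requires >=2 values")
    if np.ptp(v) == 0:  # all replicates identical: defined limit
        if v[0] == mu0:
            logger.debug("one_sample_t: zero variance at mu0; returning t=0, p=1")
            return 0.0, 1.0
        return float(np.sign(v[0] - mu0)) * np.inf, 0.0
    res = sps.ttest_1samp(v, mu0)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(a, b, *, pooled: bool = False) -> tuple[float, float]:
    """Classical two-sample t-test (Welch by default, pooled on request)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires >=2 values per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both samples constant
        if a[0] == b[0]:
            logger.debug("two_sample_t: both samples constant and equal; t=0, p=1")
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean())) * np.inf, 0.0
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)
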