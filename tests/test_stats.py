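import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polyshock.stats import (
    ModeratedTParams,
    adjust_by,
    moderated_t_matrix,
    one_sample_t,
    prop_test,
    two_sample_t,
)


def classical_pooled_t(x1, x2):
    """Textbook pooled-variance two-sample t, computed gene by gene."""
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    out_t, out_p = [], []
    for a, b in zip(x1, x2):
        s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        se = np.sqrt(s2 * (1 / n1 + 1 / n2))
        t = (a.mean() - b.mean()) / se if se > 0 else 0.0
        out_t.append(t)
        out_p.append(2 * sps.t.sf(abs(t), df))
    return np.array(out_t), np.array(out_p)


def by_step_up(p):
    """Benjamini-Yekutieli step-up computed directly from its definition."""
    p = np.asarray(p, float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * c_m / rank * p[order[rank - 1]])
        q[order[rank - 1]] = min(running, 1.0)
    return q


@pytest.fixture()
def twenty_gene_fixture():
    rng = np.random.default_rng(2024)
    x1 = rng.normal(8, 1, (20, 1)) + rng.normal(0, 0.5, (20, 3))
    x2 = rng.normal(8, 1, (20, 1)) + rng.normal(0, 0.5, (20, 4))
    return x1, x2


class TestModeratedT:
    def test_d0_zero_equals_classical_t(self, twenty_gene_fixture):
        x1, x2 = twenty_gene_fixture
        res = moderated_t_matrix(x1, x2, ordinary=True)
        t_ref, p_ref = classical_pooled_t(x1, x2)
        np.testing.assert_allclose(res["t_stat"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], p_ref, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_exactly(self, twenty_gene_fixture):
        x1, x2 = twenty_gene_fixture
        params = ModeratedTParams(d0=np.inf, s0_sq=0.3)
        res = moderated_t_matrix(x1, x2, params=params)
        se = np.sqrt(0.3 * (1 / 3 + 1 / 4))
        np.testing.assert_allclose(res["t_stat"], res["log_fc"] / se, rtol=1e-12)

    def test_identical_groups_give_t0_p1(self):
        x = np.tile([[5.0, 5.0, 5.0]], (4, 1))
        res = moderated_t_matrix(x, x.copy())
        assert (res["t_stat"] == 0).all()
        assert (res["p_value"] == 1).all()

    def test_zero_variance_fallback_is_ordinary(self, caplog):
        x1 = np.tile([[5.0, 5.0]], (3, 1))
        x2 = np.array([[5.0, 5.0], [6.0, 6.0], [4.0, 4.0]])
        res = moderated_t_matrix(x1, x2)
        np.testing.assert_array_equal(res["p_value"], [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(np.sign(res["t_stat"]), [0.0, -1.0, 1.0])

    def test_group_of_one_replicate_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            moderated_t_matrix(np.ones((3, 1)), np.ones((3, 3)))

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent cross-check against the Bioconductor reference."""
        rng = np.random.default_rng(7)
        sd = rng.uniform(0.1, 1.0, 60)
        x1 = rng.normal(7, 1, (60, 1)) + rng.normal(0, 1, (60, 3)) * sd[:, None]
        x2 = x1.mean(1)[:, None] + rng.normal(0, 1, (60, 3)) * sd[:, None]
        pd.DataFrame(np.hstack([x1, x2])).to_csv(tmp_path / "mat.tsv", sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/mat.tsv"))\n'
            "design <- cbind(g1=c(1,1,1,0,0,0), g2=c(0,0,0,1,1,1))\n"
            "fit <- lmFit(x, design)\n"
            "fit <- contrasts.fit(fit, makeContrasts(g1-g2, levels=design))\n"
            "fit <- eBayes(fit)\n"
            "out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior, s0=fit$s2.prior)\n"
            f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = moderated_t_matrix(x1, x2)
        params = res.attrs["params"]
        np.testing.assert_allclose(params.d0, ref["d0"][0], rtol=1e-6)
        np.testing.assert_allclose(params.s0_sq, ref["s0"][0], rtol=1e-6)
        np.testing.assert_allclose(res["t_stat"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-8)


class TestAdjustBY:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_by([0.03]), [0.03])

    def test_hand_computed_three_values(self):
        # m=3, c(3)=11/6: q = min_j>=i 3*(11/6)/j * p_(j) -> all 0.055
        np.testing.assert_allclose(adjust_by([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055])

    def test_empty_input(self):
        assert adjust_by([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_definition_and_dominates_raw(self, p):
        q = adjust_by(p)
        np.testing.assert_allclose(q, by_step_up(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = adjust_by(p)
        q_perm = adjust_by([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = adjust_by(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPropTest:
    def test_divergent_proportions_significant(self):
        assert prop_test(46, 159, 126, 208).p_value < 0.05

    def test_similar_proportions_nonsignificant(self):
        assert prop_test(188, 291, 100, 154).p_value > 0.05

    def test_identical_proportions_give_zero_chi(self):
        res = prop_test(5, 10, 5, 10)
        assert res.chi_sq == 0.0
        assert res.p_value == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prop_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            prop_test(3, 2, 1, 2)

    def test_matches_textbook_yates_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1, n2 = rng.integers(5, 200, 2)
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            a, b, c, d = x1, n1 - x1, x2, n2 - x2
            n = a + b + c + d
            num = max(0.0, abs(a * d - b * c) - n / 2.0) ** 2 * n
            den = (a + b) * (c + d) * (a + c) * (b + d)
            chi_ref = num / den
            res = prop_test(x1, int(n1), x2, int(n2))
            np.testing.assert_allclose(res.chi_sq, chi_ref, atol=1e-10)
            np.testing.assert_allclose(res.p_value, sps.chi2.sf(chi_ref, 1), atol=1e-10)


class TestPlainT:
    def test_constant_at_mu0(self):
        assert one_sample_t([0.5, 0.5, 0.5], 0.5) == (0.0, 1.0)

    def test_constant_off_mu0(self):
        t, p = one_sample_t([0.7, 0.7, 0.7], 0.5)
        assert t == np.inf and p == 0.0

    def test_separated_samples_significant(self):
        a, b = (0.70, 0.72, 0.71), (0.50, 0.49, 0.51)
        t, p = two_sample_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        np.testing.assert_allclose((t, p), (t_ref, p_ref))
        assert p < 0.05

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)

    def test_pooled_option_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 4), rng.normal(0, 2, 6)
        t, p = two_sample_t(a, b, pooled=True)
        ref = sps.ttest_ind(a, b, equal_var=True)
        np.testing.assert_allclose((t, p), (ref.statistic, ref.pvalue))

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.5], 0.5)
        with pytest.raises(ValueError):
            two_sample_t([0.5], [0.4, 0.6])
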