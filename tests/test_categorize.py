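import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from polyshock.categorize import (
    ELD_PATTERNS,
    classify_parental,
    classify_pattern,
    classify_tissue,
    compute_mpv,
    detection_filter,
    summarize_categories,
)
from polyshock.recovery import pattern_recovery


def constant_groups(values_by_group, n_genes, n_reps=3):
    """Replicate-constant group matrices for exact decision-tree fixtures."""
    return {
        key: np.tile(np.asarray(v, float)[:, None], (1, n_reps))
        for key, v in values_by_group.items()
    }


class TestDetectionFilter:
    def test_gene_below_threshold_everywhere_removed(self):
        ds = make_dataset(
            ["g1", "g2"],
            constant_groups({("parentA", ""): [3.0, 8.0], ("parentB", ""): [4.0, 8.0]}, 2),
        )
        flags, filtered = detection_filter(ds, threshold=5.0)
        assert filtered.gene_ids == ["g2"]

    def test_presence_in_one_genotype_is_enough(self):
        ds = make_dataset(
            ["g1"],
            constant_groups({("parentA", ""): [8.0], ("parentB", ""): [2.0]}, 1),
        )
        _, filtered = detection_filter(ds, threshold=5.0)
        assert filtered.gene_ids == ["g1"]

    def test_presence_requires_all_replicates(self):
        ds = make_dataset(["g1"], {("parentA", ""): np.array([[8.0, 8.0, 4.0]])})
        _, filtered = detection_filter(ds, threshold=5.0)
        assert filtered.gene_ids == []

    def test_planted_absent_count(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(6, 10, 100)
        vals[:30] = 2.0  # planted all-absent
        ds = make_dataset(
            [f"g{i}" for i in range(100)],
            constant_groups({("parentA", ""): vals, ("parentB", ""): vals}, 100),
        )
        _, filtered = detection_filter(ds, threshold=5.0)
        assert filtered.shape[0] == 70


class TestComputeMpv:
    def test_symmetric_parents(self):
        ds = make_dataset(
            ["g1"],
            constant_groups({("parentA", ""): [7.0], ("parentB", ""): [7.0]}, 1),
        )
        res = compute_mpv(ds, "leaf", "computed")
        assert res.values.iloc[0] == pytest.approx(7.0)

    def test_linear_scale_average(self):
        # parents at log2 3 and 5: MPV = log2((8+32)/2) = log2(20)
        ds = make_dataset(
            ["g1"],
            constant_groups({("parentA", ""): [3.0], ("parentB", ""): [5.0]}, 1),
        )
        res = compute_mpv(ds, "leaf", "computed")
        assert res.values.iloc[0] == pytest.approx(np.log2(20), abs=1e-12)

    def test_measured_mix_uses_mix_columns(self):
        ds = make_dataset(
            ["g1"],
            constant_groups(
                {("parentA", ""): [3.0], ("parentB", ""): [5.0], ("mix", ""): [4.5]}, 1
            ),
        )
        res = compute_mpv(ds, "leaf", "measured_mix")
        assert res.labels == ds.sample_ids(role="mix")
        assert res.values.iloc[0] == pytest.approx(4.5)

    def test_unequal_parent_replicates_pair_to_minimum(self, caplog):
        ds = make_dataset(
            ["g1"],
            {
                ("parentA", ""): np.array([[3.0, 3.0, 3.0]]),
                ("parentB", ""): np.array([[5.0, 5.0]]),
            },
        )
        with caplog.at_level("WARNING", logger="polyshock.categorize"):
            res = compute_mpv(ds, "leaf", "computed")
        assert res.replicates.shape == (1, 2)
        assert any("unequal" in r.message for r in caplog.records)


class TestClassifyParental:
    def test_identical_parents_are_pec(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(6, 10, 30)
        noise = rng.normal(0, 0.2, (30, 6))
        ds = make_dataset(
            [f"g{i}" for i in range(30)],
            {
                ("parentA", ""): base[:, None] + noise[:, :3],
                ("parentB", ""): base[:, None] + noise[:, 3:],
            },
        )
        res = classify_parental(ds, "leaf")
        assert (res["parental_status"] == "PEC").mean() > 0.9
        assert (res.loc[res["parental_status"] == "PEC", "ped_direction"] == "none").all()

    def test_planted_divergence_recovered_with_direction(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(6, 10, 40)
        lfc = np.where(np.arange(40) % 2 == 0, 2.0, -2.0)
        ds = make_dataset(
            [f"g{i}" for i in range(40)],
            {
                ("parentA", ""): base[:, None] + lfc[:, None] / 2 + rng.normal(0, 0.2, (40, 3)),
                ("parentB", ""): base[:, None] - lfc[:, None] / 2 + rng.normal(0, 0.2, (40, 3)),
            },
        )
        res = classify_parental(ds, "leaf")
        assert (res["parental_status"] == "PED").all()
        expect = np.where(lfc > 0, "A_higher", "B_higher")
        assert (res["ped_direction"].to_numpy() == expect).all()

    def test_simulated_ped_fraction_recovered(self, noisy_sim):
        cfg, ds, truth, _ = noisy_sim
        _, filtered = detection_filter(ds, tissue="leaf")
        res = classify_parental(filtered, "leaf")
        merged = res.merge(truth.parental, on="gene_id")
        agree = (merged["parental_status"] == merged["status"]).mean()
        assert agree > 0.95
        realized = (merged["parental_status"] == "PED").mean()
        planted = (merged["status"] == "PED").mean()
        assert abs(realized - planted) < 0.05


class TestClassifyPattern:
    def _exact_calls(self, groups, status=None):
        n = len(next(iter(groups.values())))
        genes = [f"g{i}" for i in range(n)]
        ds = make_dataset(genes, constant_groups(groups, n))
        parental = classify_parental(ds, "leaf")
        if status is not None:
            parental["parental_status"] = status
        return classify_pattern(ds, "leaf", "S5", parental)

    def test_pec_transgressive_up_is_over_tre(self):
        calls = self._exact_calls(
            {("parentA", ""): [6.0], ("parentB", ""): [6.0], ("mix", ""): [6.0],
             ("polyploid", "S5"): [9.0]}
        )
        assert calls.loc[0, "pattern"] == "over_tre"
        assert calls.loc[0, "additivity"] == "nonadditive"

    def test_ped_matching_higher_parent_is_eld_high(self):
        calls = self._exact_calls(
            {("parentA", ""): [9.0], ("parentB", ""): [5.0],
             ("mix", ""): [np.log2((2**9.0 + 2**5.0) / 2)],
             ("polyploid", "S5"): [9.0]}
        )
        assert calls.loc[0, "pattern"] == "eld_high_parentA"

    def test_ped_matching_lower_parent_is_eld_low(self):
        calls = self._exact_calls(
            {("parentA", ""): [9.0], ("parentB", ""): [5.0],
             ("mix", ""): [np.log2((2**9.0 + 2**5.0) / 2)],
             ("polyploid", "S5"): [5.0]}
        )
        assert calls.loc[0, "pattern"] == "eld_low_parentB"

    def test_all_groups_identical_is_constant_additive(self):
        calls = self._exact_calls(
            {("parentA", ""): [7.0], ("parentB", ""): [7.0], ("mix", ""): [7.0],
             ("polyploid", "S5"): [7.0]}
        )
        assert calls.loc[0, "pattern"] == "constant"
        assert calls.loc[0, "additivity"] == "additive"

    def test_missing_generation_raises(self, zero_sim):
        _, ds, truth, _ = zero_sim
        parental = classify_parental(ds, "leaf")
        with pytest.raises(ValueError, match="S99"):
            classify_pattern(ds, "leaf", "S99", parental)


class TestPipelineProperties:
    def test_partition_and_expression_space(self, noisy_sim):
        cfg, ds, truth, _ = noisy_sim
        calls = classify_tissue(ds, "leaf", cfg.generations)
        # exactly one call per retained gene x generation
        assert not calls.duplicated(["gene_id", "generation"]).any()
        sizes = calls.groupby("generation").size()
        assert sizes.nunique() == 1
        # Fig-2C-style constraint: PEC genes never receive an ELD pattern
        pec = calls[calls["parental_status"] == "PEC"]
        assert not pec["pattern"].isin(ELD_PATTERNS).any()
        # additivity label and pattern label agree
        add = calls["additivity"] == "additive"
        assert (calls.loc[add, "pattern"].isin(["constant", "additive"])).all()
        assert (~calls.loc[~add, "pattern"].isin(["constant", "additive"])).all()

    def test_zero_noise_recovers_planted_patterns_exactly(self, zero_sim):
        cfg, ds, truth, _ = zero_sim
        calls = classify_tissue(ds, "leaf", cfg.generations)
        acc, n = pattern_recovery(calls, truth)
        assert acc == 1.0
        assert n > 0

    def test_relaxing_alpha_never_reverts_to_additive(self, noisy_sim):
        cfg, ds, truth, _ = noisy_sim
        strict = classify_tissue(ds, "leaf", ("S5",), alpha=0.01)
        loose = classify_tissue(ds, "leaf", ("S5",), alpha=0.10)
        merged = strict.merge(loose, on="gene_id", suffixes=("_s", "_l"))
        went_back = (merged["additivity_s"] == "nonadditive") & (
            merged["additivity_l"] == "additive"
        )
        assert not went_back.any()


class TestSummarize:
    def test_counts_partition_each_stratum(self, noisy_sim):
        cfg, ds, truth, _ = noisy_sim
        calls = classify_tissue(ds, "leaf", cfg.generations)
        summary = summarize_categories(calls)
        per_stratum = summary.pattern_counts.groupby(["tissue", "generation"])["n"].sum()
        for (tis, gen), total in per_stratum.items():
            assert total == len(calls[(calls["tissue"] == tis) & (calls["generation"] == gen)])
        props = summary.pattern_counts.groupby(["tissue", "generation"])["proportion"].sum()
        np.testing.assert_allclose(props, 1.0)

    def test_simple_proportion(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "tissue": "leaf",
                "generation": "S5",
                "parental_status": ["PEC"] * 5 + ["PED"] * 5,
                "ped_direction": "none",
                "additivity": ["nonadditive"] * 4 + ["additive"] * 6,
                "pattern": ["over_tre"] * 4 + ["constant"] * 6,
                "mpv": 7.0,
            }
        )
        summary = summarize_categories(calls)
        nonadd = summary.pattern_counts.query("pattern == 'over_tre'")["proportion"].iloc[0]
        assert nonadd == pytest.approx(0.4)

    def test_recovered_category_mix_tracks_planted(self, noisy_sim):
        cfg, ds, truth, _ = noisy_sim
        calls = classify_tissue(ds, "leaf", cfg.generations)
        acc, _ = pattern_recovery(calls, truth)
        assert acc > 0.9
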