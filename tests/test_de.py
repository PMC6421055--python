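import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import altox
from altox.de import (
    _conditional_two_sided, bh_fdr, exact_test, fold_changes, rank_by_significance,
)
from altox.io_design import ComparisonGrouping, CountMatrix, ValidationError
from altox.normalize import NormalizationResult


def _grouping(stress, control, name="g"):
    return ComparisonGrouping(name, stress, control)


class TestFoldChanges:
    def test_arithmetic(self):
        cpm = pd.DataFrame({"s1": [8.0], "c1": [2.0]}, index=["g1"])
        fc = fold_changes(cpm, _grouping(["s1"], ["c1"]), pseudo=0.0)
        assert fc.loc[0, "fc"] == pytest.approx(4.0)
        assert fc.loc[0, "log2fc"] == pytest.approx(2.0)

    def test_equal_means_give_unit_fc(self):
        cpm = pd.DataFrame({"s1": [5.0], "c1": [5.0]}, index=["g1"])
        fc = fold_changes(cpm, _grouping(["s1"], ["c1"]), pseudo=0.5)
        assert fc.loc[0, "fc"] == pytest.approx(1.0)
        assert fc.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_missing_arm_sample_rejected(self):
        cpm = pd.DataFrame({"s1": [5.0]}, index=["g1"])
        with pytest.raises(ValidationError):
            fold_changes(cpm, _grouping(["s1"], ["nope"]))

    def test_pooled_logfc_bounded_by_genotype_logfcs(self, small_sim):
        """With balanced replicates the pooled 'all' log2FC lies within the
        per-genotype range (mediant inequality)."""
        cm, design, _ = small_sim
        norm = altox.tmm_factors(cm)
        cpm = altox.compute_cpm(cm, norm, effective=True)
        tables = {g: fold_changes(cpm, design.grouping(g), pseudo=0.5)
                  for g in design.genotypes}
        pooled = fold_changes(cpm, design.grouping("all"), pseudo=0.5)
        per_geno = pd.DataFrame(
            {g: t.set_index("gene_id")["log2fc"] for g, t in tables.items()}
        )
        pooled_lfc = pooled.set_index("gene_id")["log2fc"]
        assert (pooled_lfc >= per_geno.min(axis=1) - 1e-9).all()
        assert (pooled_lfc <= per_geno.max(axis=1) + 1e-9).all()

    def test_planted_effect_recovered_per_genotype(self):
        """Genotype-level fold changes recover a planted log2FC of 2.3
        (the published AGL62 magnitude) without bias and within the
        generator's own ±3 sd error bands for well-expressed genes."""
        cfg = altox.SimulationConfig(
            n_genes=2000, seed=3, effect_size=2.3,
            class_fractions={"null": 0.8, "resistant_specific_up": 0.2},
        )
        cm, design, truth = altox.simulate_counts(cfg)
        norm = altox.tmm_factors(cm)
        cpm = altox.compute_cpm(cm, norm, effective=True)
        genotype = design.genotypes_in("resistant")[0]
        fc = fold_changes(cpm, design.grouping(genotype), pseudo=0.5)
        lfc = fc.set_index("gene_id")["log2fc"]
        sel = truth.loc[(truth["gene_class"] == "resistant_specific_up")
                        & (truth["baseline_mean"] >= 50)]
        assert len(sel) > 50
        err = lfc.loc[sel["gene_id"]].to_numpy() - 2.3
        mu = sel["baseline_mean"].to_numpy()
        phi = sel["dispersion"].to_numpy()
        pred_sd = np.sqrt((1 / mu + phi) / 2
                          + (1 / (mu * 2 ** 2.3) + phi) / 2) / np.log(2)
        assert abs(np.median(err)) <= 0.35
        assert (np.abs(err / pred_sd) <= 3).mean() >= 0.95


class TestExactTest:
    def test_identical_counts_equal_arms_give_p_one(self):
        cm = CountMatrix(pd.DataFrame(
            {"s1": [40, 7], "s2": [40, 7], "c1": [40, 7], "c2": [40, 7]},
            index=["g1", "g2"]))
        libs = pd.Series([1000] * 4, index=cm.sample_ids)
        cm.library_sizes = libs
        pv = exact_test(cm, _grouping(["s1", "s2"], ["c1", "c2"]),
                        NormalizationResult(pd.Series(1.0, index=cm.sample_ids),
                                            libs.astype(float), "s1"))
        assert np.allclose(pv, 1.0)

    def test_closed_form_binomial_oracle(self):
        """φ=0, one replicate per arm, equal libraries, counts 0 vs 10 →
        two-sided p = 2 × (1/2)^10."""
        assert _conditional_two_sided(10, 10, 1, 1, 0.0) == pytest.approx(
            2 * (0.5 ** 10), abs=1e-15)
        assert _conditional_two_sided(0, 10, 1, 1, 0.0) == pytest.approx(
            2 * (0.5 ** 10), abs=1e-15)

    def test_p_in_unit_interval_and_central_cap(self):
        # symmetric split doubles to > 1 and is capped
        assert _conditional_two_sided(5, 10, 1, 1, 0.3) == 1.0
        assert 0.0 < _conditional_two_sided(9, 10, 1, 1, 0.3) <= 1.0

    def test_swapping_arms_preserves_p(self, small_sim):
        cm, design, _ = small_sim
        norm = altox.tmm_factors(cm)
        g = design.grouping("resistant")
        pv = exact_test(cm, g, norm)
        pv_swapped = exact_test(
            cm, ComparisonGrouping("swap", g.control_samples, g.stress_samples), norm)
        # identical up to float summation order in the dispersion estimate
        assert np.abs(pv.to_numpy() - pv_swapped.to_numpy()).max() < 1e-8

    def test_invariant_to_gene_order_and_within_arm_relabeling(self, small_sim):
        cm, design, _ = small_sim
        norm = altox.tmm_factors(cm)
        g = design.grouping("Hermes")
        pv = exact_test(cm, g, norm)
        shuffled = CountMatrix(cm.counts.iloc[::-1], cm.library_sizes)
        pv_shuffled = exact_test(shuffled, g, norm)
        assert np.allclose(pv.loc[pv_shuffled.index].to_numpy(),
                           pv_shuffled.to_numpy())
        relabeled = ComparisonGrouping(
            "r", list(reversed(g.stress_samples)), list(reversed(g.control_samples)))
        assert np.allclose(pv.to_numpy(), exact_test(cm, relabeled, norm).to_numpy())

    def test_zero_arm_rejected(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0], "c1": [5]}, index=["g1"]))
        cm.library_sizes = pd.Series([100, 100], index=["s1", "c1"])
        norm = NormalizationResult(pd.Series(1.0, index=["s1", "c1"]),
                                   cm.library_sizes.astype(float), "c1")
        with pytest.raises(ValidationError):
            exact_test(cm, _grouping(["s1"], ["c1"]), norm)


class TestRanking:
    def test_tie_rule_p_then_abs_lfc_then_gene(self):
        table = pd.DataFrame({
            "gene_id": ["gene1", "gene2", "gene3"],
            "log2fc": [1.0, 0.2, 3.0],
            "p_value": [0.5, 0.001, 0.001],
        })
        ranked = rank_by_significance(table)
        assert list(ranked["gene_id"]) == ["gene3", "gene2", "gene1"]

    def test_bh_hand_computation(self):
        fdr = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_in_p(self, small_sim):
        cm, design, _ = small_sim
        norm = altox.tmm_factors(cm)
        table = altox.de_table(cm, design.grouping("all"), norm)
        assert table["p_value"].is_monotonic_increasing
        assert table["fdr"].is_monotonic_increasing
        assert table["fdr"].between(0, 1).all()

    def test_ranking_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(50)],
            "log2fc": rng.normal(size=50),
            "p_value": rng.uniform(size=50).round(2),  # force ties
        })
        a = rank_by_significance(table)
        b = rank_by_significance(table.sample(frac=1.0, random_state=1))
        assert list(a["gene_id"]) == list(b["gene_id"])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_log2fc_is_log2_of_fc(self, seed):
        rng = np.random.default_rng(seed)
        cpm = pd.DataFrame(rng.uniform(0, 100, size=(5, 4)),
                           index=[f"g{i}" for i in range(5)],
                           columns=["s1", "s2", "c1", "c2"])
        fc = fold_changes(cpm, _grouping(["s1", "s2"], ["c1", "c2"]), pseudo=0.5)
        assert np.allclose(fc["log2fc"], np.log2(fc["fc"]))
        assert (fc["fc"] > 0).all()
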