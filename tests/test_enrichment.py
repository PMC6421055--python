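from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
import pytest

import altox
from altox.enrichment import (
    build_top_lists, hypergeom_enrich, wallenius_enrich, enrich_top_lists,
)
from altox.io_design import GOAnnotationMap, ValidationError


def _map_single_term(universe, annotated, term="GO:1"):
    return GOAnnotationMap({g: {term} for g in annotated})


def _ranked(n, n_sig, n_up_sig):
    """Ranked DE table: first n_sig rows significant, n_up_sig of them up."""
    p = np.concatenate([np.linspace(1e-6, 0.049, n_sig),
                        np.linspace(0.051, 0.99, n - n_sig)])
    lfc = np.zeros(n)
    lfc[:n_sig] = [1.0 if i < n_up_sig else -1.0 for i in range(n_sig)]
    lfc[n_sig:] = 0.5
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "log2fc": lfc, "p_value": p})


class TestTopLists:
    def test_counting_under_stated_rules(self):
        """400 genes, 220 significant, 130 up → up-lists 50/100/130/130."""
        # build: significant block interleaves 130 up then 90 down
        with pytest.warns(UserWarning):
            lists = build_top_lists(_ranked(400, 220, 130))
        up = lists["up"]
        assert [len(up[k]) for k in ("50", "100", "300", "all")] == [50, 100, 130, 130]
        down = lists["down"]
        assert [len(down[k]) for k in ("50", "100", "300", "all")] == [50, 90, 90, 90]

    def test_zero_logfc_in_neither_direction(self):
        t = pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [0.0, 1.0],
                          "p_value": [0.01, 0.01]})
        lists = build_top_lists(t, sizes=[1])
        assert "a" not in lists["up"]["all"] and "a" not in lists["down"]["all"]
        assert lists["up"]["all"] == ["b"]

    def test_short_list_returned_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            lists = build_top_lists(_ranked(100, 30, 30), sizes=[50])
        assert len(lists["up"]["50"]) == 30


class TestHypergeometric:
    def test_brute_force_enumeration_oracle(self):
        """N=20, K=5, n=5, k=4 → p = (C(5,4)C(15,1)+C(5,5)C(15,0))/C(20,5)."""
        universe = [f"g{i}" for i in range(20)]
        annotated = universe[:5]
        top = universe[:4] + [universe[10]]  # overlap k = 4
        res = hypergeom_enrich(top, universe, GOAnnotationMap(
            {g: {"GO:1"} for g in annotated}))
        expected = (comb(5, 4) * comb(15, 1) + comb(5, 5)) / comb(20, 5)
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(76 / 15504)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(universe[5:8], universe,
                               _map_single_term(universe, universe[:3]))
        assert res.loc[0, "p_value"] == 1.0

    def test_term_annotating_whole_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(universe[:4], universe,
                               _map_single_term(universe, universe))
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_top_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="alien"):
            hypergeom_enrich(["alien"], ["g1", "g2", "g3"],
                             _map_single_term(None, ["g1", "g2", "g3"]))

    def test_pmf_sums_to_one_and_p_monotone_in_k(self):
        from scipy import stats
        N, K, n = 20, 6, 7
        pmf = [stats.hypergeom.pmf(k, N, K, n) for k in range(n + 1)]
        assert sum(pmf) == pytest.approx(1.0, abs=1e-12)
        ps = [stats.hypergeom.sf(k - 1, N, K, n) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_small_terms_excluded_from_testing(self):
        universe = [f"g{i}" for i in range(10)]
        annot = GOAnnotationMap({"g0": {"GO:small"}, "g1": {"GO:small"},
                                 **{g: {"GO:big"} for g in universe[:5]}})
        res = hypergeom_enrich(universe[:3], universe, annot, min_term_size=3)
        assert set(res["term_id"]) == {"GO:big"}


def wallenius_pmf_enumeration(N, K, n, odds):
    """Sequential weighted-urn probabilities P(k in-group among n draws)."""

    @lru_cache(maxsize=None)
    def prob(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i + j == 0:
            return 1.0
        total = 0.0
        if i > 0:
            k_rem, out_rem = K - (i - 1), N - K - j
            total += prob(i - 1, j) * odds * k_rem / (odds * k_rem + out_rem)
        if j > 0:
            k_rem, out_rem = K - i, N - K - (j - 1)
            total += prob(i, j - 1) * out_rem / (odds * k_rem + out_rem)
        return total

    return [prob(k, n - k) for k in range(n + 1)]


class TestWallenius:
    def _setup(self):
        universe = [f"g{i}" for i in range(20)]
        annotated = universe[:5]
        top = universe[:4] + [universe[10]]
        return universe, annotated, top

    def test_unit_weights_reduce_to_hypergeometric(self):
        universe, annotated, top = self._setup()
        annot = GOAnnotationMap({g: {"GO:1"} for g in annotated})
        h = hypergeom_enrich(top, universe, annot)
        w = wallenius_enrich(top, universe, annot, {g: 1.0 for g in universe})
        assert abs(h.loc[0, "p_value"] - w.loc[0, "p_value"]) < 1e-9

    def test_brute_force_urn_oracle_odds_two(self):
        """Upper tail at k=4 matches exact enumeration of the weighted urn."""
        universe, annotated, top = self._setup()
        annot = GOAnnotationMap({g: {"GO:1"} for g in annotated})
        # weights: annotated genes 2, others 1 → odds exactly 2
        weights = {g: (2.0 if g in annotated else 1.0) for g in universe}
        res = wallenius_enrich(top, universe, annot, weights)
        pmf = wallenius_pmf_enumeration(20, 5, 5, 2.0)
        assert sum(pmf) == pytest.approx(1.0, abs=1e-12)
        expected = pmf[4] + pmf[5]
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-6)

    def test_doubling_weights_leaves_p_unchanged(self):
        universe, annotated, top = self._setup()
        annot = GOAnnotationMap({g: {"GO:1"} for g in annotated})
        w1 = {g: (2.0 if g in annotated else 1.0) for g in universe}
        w2 = {g: 2 * v for g, v in w1.items()}
        a = wallenius_enrich(top, universe, annot, w1).loc[0, "p_value"]
        b = wallenius_enrich(top, universe, annot, w2).loc[0, "p_value"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_non_positive_weight_rejected(self):
        universe, annotated, top = self._setup()
        annot = GOAnnotationMap({g: {"GO:1"} for g in annotated})
        weights = {g: 1.0 for g in universe}
        weights[universe[0]] = 0.0
        with pytest.raises(ValidationError, match="positive"):
            wallenius_enrich(top, universe, annot, weights)


class TestPlantedTermRecovery:
    def test_planted_term_attains_smallest_fdr(self):
        """A GO term covering 80% of divergent genes ranks first by BH FDR
        among a 50-term map in the up-list enrichment, across seeded reruns."""
        cfg = altox.SimulationConfig(
            n_genes=1200, seed=31, effect_size=3.0,
            class_fractions={"null": 0.9, "divergent_opposite": 0.1},
        )
        cm, design, truth = altox.simulate_counts(cfg)
        model = altox.AluminumResponseModel(cm, design)
        res = model.fit(groupings=["resistant"])
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            annot, planted = altox.simulate_go_map(truth, n_terms=50, seed=100 + rep)
            enr = res.enrich(annot, grouping="resistant")
            stratum = enr.loc[(enr["direction"] == "up") & (enr["top_size"] == "all")]
            best = stratum.sort_values(["bh_fdr", "p_value"]).iloc[0]
            hits += best["term_id"] == planted
        assert hits / n_rep >= 0.95
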