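import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracle import brute_force_integration
from gwsig import (
    SynthConfig,
    WeightVector,
    equal_weights,
    generate,
    gwgs,
    gwgs_table,
    gwrs,
    gwrs_max,
    integrate_datasets,
    rhodes_sp,
    top_k,
)
from gwsig.errors import ConfigError, DataError
from gwsig.preprocess import GeneMatrix, build_universe
from gwsig.scoring import DEScoreTable, GWGSTable, fold_change, rank_genes, t_test_p


def _gm(values, scale_flag="log2", genes=None, n_control=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    n_control = n_control if n_control is not None else n // 2
    samples = [f"s{i}" for i in range(n)]
    labels = {s: ("control" if i < n_control else "case") for i, s in enumerate(samples)}
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return GeneMatrix(
        study_id="t",
        gene_symbols=genes,
        sample_ids=samples,
        labels=labels,
        values=values,
        scale_flag=scale_flag,
        provenance={g: "p" for g in genes},
    )


class TestFoldChange:
    def test_no_change_scores_zero(self):
        table = fold_change(_gm([[3.0, 3.0, 3.0, 3.0]]))
        assert table.scores.iloc[0] == 0.0

    def test_linear_dyadic_ratio(self):
        table = fold_change(_gm([[2.0, 2.0, 4.0, 4.0]], scale_flag="linear"))
        assert table.scores.iloc[0] == pytest.approx(1.0)

    def test_log2_hand_means(self):
        table = fold_change(_gm([[2.0, 4.0, 5.0, 7.0]]))
        assert table.scores.iloc[0] == pytest.approx(3.0)

    def test_signed_direction_keeps_sign(self):
        gm = _gm([[5.0, 5.0, 2.0, 2.0]])
        assert fold_change(gm, "signed").scores.iloc[0] == pytest.approx(-3.0)
        assert fold_change(gm, "absolute").scores.iloc[0] == pytest.approx(3.0)

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(DataError):
            fold_change(_gm([[0.0, 1.0, 2.0, 3.0]], scale_flag="linear"))


class TestTTest:
    def test_separated_classes_significant(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 1, 10)
        case = rng.normal(8, 1, 10)
        gm = _gm([np.concatenate([ctrl, case])], n_control=10)
        p = t_test_p(gm).scores.iloc[0]
        assert p < 0.01
        # reference: Welch statistic evaluated against the t distribution directly
        t_stat, ref_p = stats.ttest_ind(case, ctrl, equal_var=False)
        assert p == pytest.approx(ref_p)

    def test_null_case_large_p(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        gm = _gm([x], n_control=3)
        assert t_test_p(gm).scores.iloc[0] == pytest.approx(1.0)

    def test_degenerate_equal_constant_classes(self):
        gm = _gm([[5.0, 5.0, 5.0, 5.0]])
        assert t_test_p(gm).scores.iloc[0] == 1.0

    def test_single_sample_class_rejected(self):
        with pytest.raises(DataError):
            t_test_p(_gm([[1.0, 2.0, 3.0]], n_control=1))


def _universe_for(genes, study="t"):
    gm = _gm(np.zeros((len(genes), 4)), genes=list(genes))
    gm.study_id = study
    return build_universe([gm], delta=0)


class TestRankGenes:
    def test_descending_sort(self):
        table = DEScoreTable("t", pd.Series({"A": 3.0, "B": 1.0, "C": 2.0}), "fold_change")
        ranks = rank_genes(table, _universe_for(["A", "B", "C"]))
        assert ranks.to_dict() == {"A": 1.0, "C": 2.0, "B": 3.0}

    def test_mean_rank_ties(self):
        table = DEScoreTable("t", pd.Series({"A": 2.0, "B": 2.0, "C": 1.0}), "fold_change")
        ranks = rank_genes(table, _universe_for(["A", "B", "C"]))
        assert ranks["A"] == ranks["B"] == 1.5
        assert ranks["C"] == 3.0

    def test_pvalues_rank_ascending(self):
        table = DEScoreTable("t", pd.Series({"A": 0.01, "B": 0.5}), "t_test_p")
        ranks = rank_genes(table, _universe_for(["A", "B"]))
        assert ranks["A"] == 1.0

    def test_absent_gene_gets_missing_marker(self):
        gm_a = _gm(np.zeros((2, 4)), genes=["A", "B"])
        gm_a.study_id = "s1"
        gm_b = _gm(np.zeros((2, 4)), genes=["A", "C"])
        gm_b.study_id = "s2"
        universe = build_universe([gm_a, gm_b], delta=1)
        table = DEScoreTable("s1", pd.Series({"A": 1.0, "B": 2.0}), "fold_change")
        ranks = rank_genes(table, universe)
        assert np.isnan(ranks["C"])
        assert ranks["B"] == 1.0

    def test_scale_invariance_of_ranks(self):
        scores = pd.Series({"A": 0.3, "B": 1.1, "C": 0.7, "D": 2.0})
        universe = _universe_for(list(scores.index))
        base = rank_genes(DEScoreTable("t", scores, "fold_change"), universe)
        scaled = rank_genes(DEScoreTable("t", scores * 17.3, "fold_change"), universe)
        pd.testing.assert_series_equal(base, scaled)


class TestGwrs:
    def test_worst_rank_scores_zero(self):
        assert gwrs(100, 100) == 0.0

    def test_rank_one_closed_form(self):
        assert gwrs(1, 24097) == pytest.approx(2 * math.log(24097), rel=1e-12)
        assert gwrs(1, 24097) == pytest.approx(20.1797, abs=1e-3)

    def test_missing_propagates(self):
        assert np.isnan(gwrs(float("nan"), 10))

    @pytest.mark.parametrize("r", [0, 0.5, 101, -3])
    def test_domain_errors(self, r):
        with pytest.raises(DataError):
            gwrs(r, 100)

    def test_log_base_changes_scale_not_order(self):
        e_scores = [gwrs(r, 50) for r in (1, 10, 50)]
        b10 = [gwrs(r, 50, log_base=10) for r in (1, 10, 50)]
        assert sorted(e_scores, reverse=True) == e_scores
        assert sorted(b10, reverse=True) == b10
        assert b10[0] == pytest.approx(e_scores[0] / math.log(10))

    @given(
        st.integers(min_value=1, max_value=10**6).flatmap(
            lambda m: st.tuples(st.just(m), st.integers(min_value=1, max_value=m))
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_range_law(self, m_r):
        m, r = m_r
        s = gwrs(r, m)
        assert 0.0 <= s <= gwrs_max(m) + 1e-12
        if r > 1:
            assert gwrs(r - 1, m) > s  # strictly decreasing in rank


class TestGwgs:
    def test_convexity_fixed_point(self):
        s, n = gwgs([7.0] * 5, equal_weights(5))
        assert s == pytest.approx(7.0)
        assert n == 5

    def test_missing_renormalizes_weights(self):
        s, n = gwgs([10.0, 10.0, np.nan, 10.0, 10.0], equal_weights(5))
        assert s == pytest.approx(10.0)
        assert n == 4

    def test_direct_weighted_sum(self):
        s, _ = gwgs([20.0, 0.0, 0.0, 0.0, 0.0], equal_weights(5))
        assert s == pytest.approx(4.0)

    def test_zero_policy_keeps_nominal_weights(self):
        s, n = gwgs([10.0, np.nan], equal_weights(2), missing_policy="zero")
        assert s == pytest.approx(5.0)
        assert n == 1

    def test_all_missing_rejected(self):
        with pytest.raises(DataError):
            gwgs([np.nan, np.nan], equal_weights(2))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            WeightVector(np.array([0.5, 0.6]))
        with pytest.raises(ConfigError):
            WeightVector(np.array([1.5, -0.5]))

    def test_equal_weights_no_missing_is_mean(self):
        rng = np.random.default_rng(4)
        s_mat = pd.DataFrame(rng.uniform(0, 10, size=(20, 5)))
        table = gwgs_table(s_mat)
        np.testing.assert_allclose(table.s_r.to_numpy(), s_mat.mean(axis=1).to_numpy())


class TestTopK:
    def _table(self, s_r, n_contrib=None):
        idx = pd.Index(list(s_r), name="gene")
        n = n_contrib or {g: 5 for g in s_r}
        return GWGSTable(
            s_r=pd.Series(s_r, index=idx, name="s_r"),
            n_contributing=pd.Series(n, index=idx, name="n_contributing"),
            weights=equal_weights(5),
        )

    def test_k_equals_m_returns_everything(self):
        table = self._table({"A": 5.0, "B": 3.0, "C": 1.0})
        assert set(top_k(table, 3).genes) == {"A", "B", "C"}

    def test_sort_prefix(self):
        table = self._table({"A": 5.0, "B": 3.0, "C": 1.0})
        assert top_k(table, 2).genes == ("A", "B")

    def test_boundary_tie_by_symbol(self):
        table = self._table({"A": 5.0, "B": 3.0, "C": 3.0})
        assert top_k(table, 2).genes == ("A", "B")

    def test_tie_prefers_more_contributing_studies(self):
        table = self._table({"A": 3.0, "B": 3.0}, n_contrib={"A": 3, "B": 5})
        assert top_k(table, 1).genes == ("B",)

    def test_k_out_of_range_rejected(self):
        table = self._table({"A": 1.0})
        with pytest.raises(ConfigError):
            top_k(table, 2)


class TestRhodes:
    def test_all_ones_score_zero(self):
        assert rhodes_sp([1.0, 1.0, 1.0]) == 0.0

    def test_hand_evaluated_pair(self):
        assert rhodes_sp([0.05, 0.05]) == pytest.approx(11.983, abs=1e-3)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [-0.1], [1.5], [np.nan]])
    def test_domain_errors(self, bad):
        with pytest.raises(DataError):
            rhodes_sp(bad)

    def test_null_distribution_chi_square(self):
        rng = np.random.default_rng(123)
        draws = rng.uniform(size=(10_000, 5))
        sp = np.array([rhodes_sp(row) for row in draws])
        assert sp.mean() == pytest.approx(10.0, abs=0.3)  # chi2(2n) mean = 2n
        ks = stats.kstest(sp, stats.chi2(df=10).cdf).statistic
        assert ks < 0.02


class TestPipelineOracle:
    def test_matches_bruteforce_on_small_instance(self):
        cfg = SynthConfig(
            n_studies=3,
            genes_total=50,
            planted_de_count=8,
            effect_size=1.5,
            samples_per_class=5,
            seed=21,
        )
        res = generate(cfg)
        result = integrate_datasets(res.datasets, res.annotations)
        kept, s_r, top = brute_force_integration(
            res.datasets, res.annotations, delta=2, k=10
        )
        assert list(result.universe.genes) == kept
        for g in kept:
            assert result.gwgs.s_r[g] == pytest.approx(s_r[g], rel=1e-10)
        assert list(top_k(result.gwgs, 10).genes) == top

    def test_rank_invariance_to_study_rescaling(self):
        # multiplying one study's expression contrasts by a positive constant
        # must leave ranks, per-study scores and the final ordering unchanged
        cfg = SynthConfig(
            n_studies=3, genes_total=40, planted_de_count=5,
            samples_per_class=5, seed=3,
        )
        res = generate(cfg)
        base = integrate_datasets(res.datasets, res.annotations)
        ds0 = res.datasets[0]
        center = ds0.values.mean()
        ds0.values = center + (ds0.values - center) * 3.0  # rescale contrasts
        rescaled = integrate_datasets(res.datasets, res.annotations)
        pd.testing.assert_frame_equal(base.ranks, rescaled.ranks)
        pd.testing.assert_frame_equal(base.gwrs, rescaled.gwrs)
        assert base.gwgs.sorted_genes() == rescaled.gwgs.sorted_genes()
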