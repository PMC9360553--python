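from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from latgc.io_formats import ExpressionMatrix, GeneSetCollection
from latgc.ssgsea_scoring import ScoreMatrix, compare_groups, estimate_scores, ssgsea_scores


def brute_force_ssgsea(expr: pd.Series, gene_set, alpha: float) -> float:
    """Independent oracle: explicit running-sum accumulation of the weighted
    in-set ECDF minus the unweighted out-of-set ECDF, looping gene by gene."""
    genes = list(expr.index)
    ranks = stats.rankdata(expr.values)  # 1 = lowest
    order = sorted(range(len(genes)), key=lambda i: (-expr.values[i], i))
    sum_w_in = sum(abs(ranks[i]) ** alpha for i in order if genes[i] in gene_set)
    n_out = sum(1 for g in genes if g not in gene_set)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in order:
        if genes[i] in gene_set:
            cum_in += abs(ranks[i]) ** alpha / sum_w_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


@pytest.fixture
def six_gene_matrix():
    rng = np.random.default_rng(8)
    data = pd.DataFrame(
        rng.normal(5, 2, size=(6, 3)),
        index=[f"g{i}" for i in range(6)],
        columns=["s0", "s1", "s2"],
    )
    return ExpressionMatrix(data, "log2")


class TestSsgseaScores:
    def test_matches_oracle_on_all_three_gene_subsets(self, six_gene_matrix):
        """Implementation equals the brute-force running-sum oracle on every
        3-gene subset of a 6-gene matrix, for several weighting exponents."""
        genes = six_gene_matrix.gene_ids
        subsets = list(combinations(genes, 3))
        assert len(subsets) == 20
        sets = GeneSetCollection({f"set{i}": set(s) for i, s in enumerate(subsets)})
        for alpha in (0.0, 0.25, 1.0):
            scores = ssgsea_scores(six_gene_matrix, sets, alpha=alpha, normalize=False)
            for i, subset in enumerate(subsets):
                for sample in six_gene_matrix.sample_ids:
                    expected = brute_force_ssgsea(six_gene_matrix.data[sample], set(subset), alpha)
                    assert scores.data.loc[f"set{i}", sample] == pytest.approx(expected, abs=1e-10)

    def test_hand_enumerated_toy(self):
        """6-gene single-sample toy with alpha=1: score equals the value
        enumerated by hand from the running-sum definition.

        Expression g0..g5 = 6,5,4,3,2,1; set {g0,g2,g4} (ranks 6,4,2).
        Walking the descending list: steps in 6/12, out 1/3, in 4/12,
        out 2/3, in 2/12, out 3/3; partial sums of (cum_in - cum_out)
        = 1/2 + 1/6 + 1/2 + 1/6 + 1/3 + 0 = 5/3."""
        data = pd.DataFrame({"s": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]}, index=[f"g{i}" for i in range(6)])
        mat = ExpressionMatrix(data, "log2")
        sets = GeneSetCollection({"odd": {"g0", "g2", "g4"}})
        score = ssgsea_scores(mat, sets, alpha=1.0, normalize=False).data.loc["odd", "s"]
        assert score == pytest.approx(5.0 / 3.0, abs=1e-12)

    def test_identical_samples_identical_scores(self, six_gene_matrix):
        data = six_gene_matrix.data.copy()
        data["s1"] = data["s0"]
        mat = ExpressionMatrix(data, "log2")
        sets = GeneSetCollection({"a": {"g0", "g1", "g2"}})
        scores = ssgsea_scores(mat, sets, normalize=False)
        assert scores.data.loc["a", "s0"] == scores.data.loc["a", "s1"]

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_rank_invariance_under_monotone_maps(self, scale, shift):
        """Scores depend on expression only through within-sample ranks."""
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(8, 2)), index=[f"g{i}" for i in range(8)], columns=["s0", "s1"])
        sets = GeneSetCollection({"a": {"g0", "g3", "g5"}})
        base = ssgsea_scores(ExpressionMatrix(data, "log2"), sets, normalize=False)
        mapped = np.exp(scale * data) + shift  # strictly monotone
        out = ssgsea_scores(ExpressionMatrix(mapped, "log2"), sets, normalize=False)
        np.testing.assert_allclose(base.data.values, out.data.values, atol=1e-9)

    def test_alpha_zero_equals_unweighted_ecdf_oracle(self, six_gene_matrix):
        """With alpha=0 the in-set term is the plain ECDF; compare against a
        Kolmogorov-style running sum with unit weights."""
        sets = GeneSetCollection({"a": {"g1", "g4"}})
        scores = ssgsea_scores(six_gene_matrix, sets, alpha=0.0, normalize=False)
        for sample in six_gene_matrix.sample_ids:
            expr = six_gene_matrix.data[sample]
            order = expr.sort_values(ascending=False).index
            cum_in = np.cumsum([g in {"g1", "g4"} for g in order]) / 2
            cum_out = np.cumsum([g not in {"g1", "g4"} for g in order]) / 4
            assert scores.data.loc["a", sample] == pytest.approx(float(np.sum(cum_in - cum_out)), abs=1e-12)

    def test_normalization_divides_by_span(self, six_gene_matrix):
        sets = GeneSetCollection({"a": {"g0", "g1"}, "b": {"g4", "g5"}})
        raw = ssgsea_scores(six_gene_matrix, sets, normalize=False)
        norm = ssgsea_scores(six_gene_matrix, sets, normalize=True)
        span = raw.data.values.max() - raw.data.values.min()
        np.testing.assert_allclose(norm.data.values, raw.data.values / span, atol=1e-12)

    def test_insufficient_overlap_dropped(self, six_gene_matrix):
        sets = GeneSetCollection({"tiny": {"g0"}, "ok": {"g1", "g2"}})
        scores = ssgsea_scores(six_gene_matrix, sets, normalize=False)
        assert scores.feature_ids == ["ok"]

    def test_constant_sample_errors(self):
        data = pd.DataFrame({"s0": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            ssgsea_scores(ExpressionMatrix(data, "log2"), GeneSetCollection({"x": {"a", "b"}}))


class TestEstimateScores:
    def test_estimate_is_sum(self, six_gene_matrix):
        out = estimate_scores(six_gene_matrix, {"g0", "g1"}, {"g4", "g5"})
        np.testing.assert_allclose(
            out.data.loc["estimate"].values,
            (out.data.loc["stromal"] + out.data.loc["immune"]).values,
        )
        assert np.isfinite(out.data.values).all()

    def test_synthetic_immune_score_higher_in_high_group(self):
        from latgc.preprocess import log2_transform
        from latgc.synthetic_cohort import CohortConfig, generate_cohort

        config = CohortConfig(n_low=100, n_high=100, n_genes=400, n_immune_cells=3,
                              markers_per_cell=10, n_negative_link_genes=5,
                              n_mutation_genes=10, n_zero_inflated_genes=0, n_pathway_sets=2)
        cohort = generate_cohort(config, seed=17)
        log2_mat = log2_transform(cohort.expression_fpkm)
        out = estimate_scores(log2_mat, cohort.genesets["stromal_signature"], cohort.genesets["immune_signature"])
        groups = cohort.truth.latitude_group
        high = out.data.loc["immune", groups.index[groups == "high"]]
        low = out.data.loc["immune", groups.index[groups == "low"]]
        assert stats.mannwhitneyu(high, low, alternative="two-sided").pvalue < 0.05
        assert high.median() > low.median()


class TestCompareGroups:
    def _scores(self, values, samples):
        return ScoreMatrix(pd.DataFrame(values, index=["f"], columns=samples))

    def test_identical_groups_null(self):
        scores = self._scores([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], [f"s{i}" for i in range(6)])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=scores.sample_ids)
        table = compare_groups(scores, groups).table
        assert table.loc["f", "p"] == pytest.approx(1.0)
        assert table.loc["f", "direction"] == "none"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        scores = self._scores([x], [f"s{i}" for i in range(100)])
        groups = pd.Series(["low"] * 50 + ["high"] * 50, index=scores.sample_ids)
        table = compare_groups(scores, groups).table
        assert table.loc["f", "p"] < 1e-6
        assert table.loc["f", "direction"] == "higher_in_high"

    def test_exact_small_sample_matches_permutation_oracle(self):
        """Groups of 3 and 4: the exact rank-sum p equals brute force over
        all C(7,3) group assignments."""
        x = np.array([1.3, 5.2, 2.1])
        y = np.array([4.4, 0.7, 3.3, 6.1])
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs_u = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # enumeration of all assignments of 3 ranks to group x
        from itertools import combinations as comb

        n1 = len(x)
        u_obs = obs_u.statistic
        u_all = []
        for subset in comb(range(7), n1):
            r1 = ranks[list(subset)].sum()
            u = r1 - n1 * (n1 + 1) / 2
            u_all.append(u)
        u_all = np.array(u_all)
        mean_u = n1 * (7 - n1) / 2
        p_expected = np.mean(np.abs(u_all - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        scores = self._scores([pooled], [f"s{i}" for i in range(7)])
        groups = pd.Series(["high"] * 3 + ["low"] * 4, index=scores.sample_ids)
        table = compare_groups(scores, groups).table
        assert table.loc["f", "p"] == pytest.approx(p_expected, rel=1e-9)

    def test_degenerate_all_ties(self):
        scores = self._scores([[2.0] * 8], [f"s{i}" for i in range(8)])
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=scores.sample_ids)
        table = compare_groups(scores, groups).table
        assert table.loc["f", "p"] == 1.0
        assert table.loc["f", "direction"] == "none"
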