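import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latgc.io_formats import CohortClinical, ExpressionMatrix, load_table1_signature
from latgc.irpm_model import (
    IrpmSignature,
    irpm_score,
    rank_prognostic_cells,
    score_matrix,
    select_marker_genes,
    signature_from_collection,
    stratify_and_validate,
)
from latgc.preprocess import log2_transform
from latgc.ssgsea_scoring import ScoreMatrix, ssgsea_scores
from latgc.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def scored_cohort():
    """Small cohort with ssGSEA immune scores, shared across IRPM tests."""
    config = CohortConfig(n_low=60, n_high=60, n_genes=400, n_immune_cells=4,
                          markers_per_cell=10, n_negative_link_genes=8,
                          n_mutation_genes=10, n_zero_inflated_genes=0, n_pathway_sets=0)
    cohort = generate_cohort(config, seed=23)
    log2_mat = log2_transform(cohort.expression_fpkm)
    cells = [n for n in cohort.genesets.names() if n.startswith("immune_cell")]
    scores = ssgsea_scores(log2_mat, cohort.genesets.subset(cells))
    return cohort, log2_mat, scores


class TestRankPrognosticCells:
    def test_selection_and_risk_warning_semantics(self, scored_cohort):
        cohort, _, scores = scored_cohort
        cells, fits = rank_prognostic_cells(scores, cohort.clinical, n_cells=2)
        assert len(cells) == 2
        ps = [fits[c].p for c in cells]
        assert ps == sorted(ps)
        # generator cells are risk factors: fitted HRs should be > 1
        assert all(fits[c].hazard_ratio > 1 for c in cells)

    def test_single_cell_matrix(self, scored_cohort):
        cohort, _, scores = scored_cohort
        one = ScoreMatrix(scores.data.iloc[[0]], scores.normalized)
        cells, _ = rank_prognostic_cells(one, cohort.clinical, n_cells=1)
        assert cells == [scores.feature_ids[0]]

    def test_no_events_errors(self, scored_cohort):
        cohort, _, scores = scored_cohort
        table = cohort.clinical.table.copy()
        table["os_event"] = 0
        with pytest.raises(ValueError, match="events"):
            rank_prognostic_cells(scores, CohortClinical(table), n_cells=2)

    def test_protective_cell_warns(self):
        rng = np.random.default_rng(3)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(+1.5 * x))  # high score -> longer survival
        clin = CohortClinical(pd.DataFrame({"os_time": t, "os_event": 1}, index=[f"s{i}" for i in range(n)]))
        sm = ScoreMatrix(pd.DataFrame([x], index=["cell"], columns=clin.sample_ids))
        with pytest.warns(UserWarning, match="protective"):
            rank_prognostic_cells(sm, clin, n_cells=1)


class TestSelectMarkerGenes:
    def test_gene_equal_to_cell_score_selected(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(40)]
        cell = rng.normal(size=40)
        data = pd.DataFrame(rng.normal(size=(30, 40)), index=[f"g{i}" for i in range(30)], columns=samples)
        data.loc["g0"] = cell  # perfect correlation
        data.loc["g1"] = -cell
        expr = ExpressionMatrix(data, "log2")
        scores = ScoreMatrix(pd.DataFrame([cell], index=["cell"], columns=samples))
        sig = select_marker_genes(expr, scores, top_fraction=0.1)
        assert "g0" in sig.positive_genes
        assert "g1" in sig.negative_genes
        assert sig.gene_correlations.loc["g0"] == pytest.approx(1.0)

    def test_independent_genes_selected_at_chance_rate(self):
        """Genes unrelated to infiltration enter the top 5% at about the
        nominal rate (they fill the quota, so the rate is exactly the
        fraction — the informative check is that no gene repeats across
        seeds more than chance allows)."""
        hits = {}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(50)]
            data = pd.DataFrame(rng.normal(size=(100, 50)), index=[f"g{i}" for i in range(100)], columns=samples)
            scores = ScoreMatrix(pd.DataFrame(rng.normal(size=(2, 50)), index=["c1", "c2"], columns=samples))
            try:
                sig = select_marker_genes(ExpressionMatrix(data, "log2"), scores, top_fraction=0.05)
            except ValueError:
                # all top genes one-signed: a legitimate degenerate null draw
                continue
            chosen = sig.positive_genes | sig.negative_genes
            assert len(chosen) == 5  # quota = top 5% of 100 genes
            for g in chosen:
                hits[g] = hits.get(g, 0) + 1
        # under the null every gene is exchangeable: expected hits/gene = 1
        assert max(hits.values()) <= 6

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(20)]
        data = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"g{i}" for i in range(10)], columns=samples)
        data.loc["g9"] = 1.0
        scores = ScoreMatrix(pd.DataFrame(rng.normal(size=(1, 20)), index=["c"], columns=samples))
        sig = select_marker_genes(ExpressionMatrix(data, "log2"), scores, top_fraction=0.5)
        assert "g9" not in sig.positive_genes | sig.negative_genes
        assert "g9" not in sig.gene_correlations.index


class TestIrpmScore:
    def _sig(self, pos, neg):
        return IrpmSignature(frozenset(pos), frozenset(neg))

    def test_equal_sides_zero(self):
        profile = pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0, "n1": 1.0, "n2": 2.0, "n3": 3.0})
        assert irpm_score(profile, self._sig(["p1", "p2", "p3"], ["n1", "n2", "n3"])) == pytest.approx(0.0)

    def test_welch_formula_oracle(self):
        """Positive genes [5,6,7] vs negative [1,2,3]: Welch t computed
        directly from the formula t = (ma - mb)/sqrt(va/na + vb/nb)."""
        profile = pd.Series({"p1": 5.0, "p2": 6.0, "p3": 7.0, "n1": 1.0, "n2": 2.0, "n3": 3.0})
        a, b = np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0])
        expected = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        got = irpm_score(profile, self._sig(["p1", "p2", "p3"], ["n1", "n2", "n3"]))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(float(stats.ttest_ind(a, b, equal_var=False).statistic))

    def test_shift_invariance_and_sign_flip(self):
        rng = np.random.default_rng(6)
        genes = [f"p{i}" for i in range(5)] + [f"n{i}" for i in range(4)]
        profile = pd.Series(rng.normal(size=9), index=genes)
        sig = self._sig([f"p{i}" for i in range(5)], [f"n{i}" for i in range(4)])
        base = irpm_score(profile, sig)
        assert irpm_score(profile + 100.0, sig) == pytest.approx(base, rel=1e-9)
        swapped = self._sig([f"n{i}" for i in range(4)], [f"p{i}" for i in range(5)])
        assert irpm_score(profile, swapped) == pytest.approx(-base, rel=1e-9)

    def test_missing_side_errors(self):
        profile = pd.Series({"p1": 1.0, "p2": 2.0, "n1": 1.0})
        with pytest.raises(ValueError, match="missing"):
            irpm_score(profile, self._sig(["p1", "p2"], ["n1", "n2"]))

    def test_zero_variance_both_sides(self):
        profile = pd.Series({"p1": 2.0, "p2": 2.0, "n1": 1.0, "n2": 1.0})
        assert irpm_score(profile, self._sig(["p1", "p2"], ["n1", "n2"])) == np.inf
        equal = pd.Series({"p1": 2.0, "p2": 2.0, "n1": 2.0, "n2": 2.0})
        assert irpm_score(equal, self._sig(["p1", "p2"], ["n1", "n2"])) == 0.0

    def test_table1_signature_uses_all_printed_genes(self):
        """Scoring a profile over exactly the 47 printed genes uses them all:
        dropping any one gene changes the score."""
        sig = signature_from_collection(load_table1_signature())
        genes = sorted(sig.positive_genes | sig.negative_genes)
        assert len(genes) == 47
        rng = np.random.default_rng(7)
        profile = pd.Series(rng.normal(5, 2, size=47), index=genes)
        base = irpm_score(profile, sig)
        bumped = profile.copy()
        bumped["DOK2"] += 3.0
        assert irpm_score(bumped, sig) != pytest.approx(base)


class TestStratifyAndValidate:
    def test_median_cutoff_risk_assignment(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        clin = CohortClinical(pd.DataFrame(
            {"os_time": [10.0, 20, 30, 40], "os_event": [1, 1, 1, 0]}, index=list("abcd")))
        stratified, curves, p = stratify_and_validate(scores, clin, cutoff=2.5)
        assert stratified.risk.tolist() == ["low", "low", "high", "high"]
        assert set(curves) == {"high", "low"}

    def test_tie_at_cutoff_is_low_risk(self):
        scores = pd.Series([1.0, 2.0, 2.0, 4.0], index=list("abcd"))
        clin = CohortClinical(pd.DataFrame(
            {"os_time": [10.0, 20, 30, 40], "os_event": [1, 1, 1, 0]}, index=list("abcd")))
        stratified, _, _ = stratify_and_validate(scores, clin, cutoff=2.0)
        assert stratified.risk.loc["b"] == "low" and stratified.risk.loc["c"] == "low"

    def test_cutoff_above_max_errors(self):
        scores = pd.Series([1.0, 2.0], index=list("ab"))
        clin = CohortClinical(pd.DataFrame({"os_time": [1.0, 2.0], "os_event": [1, 1]}, index=list("ab")))
        with pytest.raises(ValueError, match="one side"):
            stratify_and_validate(scores, clin, cutoff=10.0)

    def test_constructed_score_stratifies_synthetic_survival(self, scored_cohort):
        cohort, log2_mat, scores = scored_cohort
        cells, _ = rank_prognostic_cells(scores, cohort.clinical, n_cells=4)
        sig = select_marker_genes(log2_mat, ScoreMatrix(scores.data.loc[cells], scores.normalized), top_fraction=0.1)
        sample_scores = score_matrix(log2_mat, sig)
        _, curves, p = stratify_and_validate(sample_scores, cohort.clinical)
        assert p < 0.05
        # worse survival in the high-risk arm at the median follow-up time
        t_med = float(np.median(cohort.clinical.table["os_time"]))
        assert curves["high"].survival_at(t_med) < curves["low"].survival_at(t_med)
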