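import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from latgc.io_formats import MutationTable
from latgc.mutation_profile import (
    compute_tmb,
    infer_subclones,
    remove_synonymous,
    select_driver_genes,
    somatic_interactions,
    top_mutated_genes,
)


def _table(samples, genes, classes=None, ref=None, alt=None):
    n = len(samples)
    return MutationTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "gene": genes,
                "variant_classification": classes or ["Missense_Mutation"] * n,
                "chrom": ["1"] * n,
                "position": range(1, n + 1),
                "ref_count": ref if ref is not None else [50] * n,
                "alt_count": alt if alt is not None else [50] * n,
            }
        )
    )


class TestRemoveSynonymous:
    def test_silent_removed(self, toy_mutations):
        out = remove_synonymous(toy_mutations)
        assert len(out) == 3
        assert "Silent" not in set(out.records["variant_classification"])

    def test_all_silent_warns_empty(self):
        mut = _table(["a", "b"], ["X", "Y"], classes=["Silent", "Silent"])
        with pytest.warns(UserWarning, match="all records removed"):
            out = remove_synonymous(mut)
        assert len(out) == 0

    def test_unknown_class_retained_with_warning(self):
        mut = _table(["a"], ["X"], classes=["Weird"])
        with pytest.warns(UserWarning, match="Weird"):
            out = remove_synonymous(mut)
        assert len(out) == 1


class TestComputeTmb:
    def test_division(self):
        mut = _table(["a"] * 380, [f"G{i}" for i in range(380)])
        res = compute_tmb(mut, capture_size_mb=38)
        assert res.table.loc["a", "tmb"] == pytest.approx(10.0)

    def test_two_samples(self):
        mut = _table(["a"] * 38 + ["b"] * 76, [f"G{i}" for i in range(114)])
        res = compute_tmb(mut, capture_size_mb=38)
        assert res.table.loc["a", "tmb"] == 1.0
        assert res.table.loc["b", "tmb"] == 2.0

    def test_absent_samples_zero(self):
        mut = _table(["a"], ["X"])
        res = compute_tmb(mut, sample_ids=["a", "b"])
        assert res.table.loc["b", "n_mutations"] == 0
        assert res.table.loc["b", "tmb"] == 0.0

    def test_linearity_and_order_invariance(self):
        rng = np.random.default_rng(4)
        samples = rng.choice(["a", "b", "c"], size=30).tolist()
        genes = [f"G{i}" for i in range(30)]
        mut = _table(samples, genes)
        shuffled = MutationTable(mut.records.sample(frac=1, random_state=1).reset_index(drop=True))
        t1 = compute_tmb(mut).table.sort_index()
        t2 = compute_tmb(shuffled).table.sort_index()
        pd.testing.assert_frame_equal(t1, t2)
        doubled = MutationTable(
            pd.concat([mut.records, mut.records.assign(position=lambda d: d.position + 1000)], ignore_index=True)
        )
        assert (compute_tmb(doubled).table.sort_index()["tmb"] == 2 * t1["tmb"]).all()

    def test_bad_capture_size(self, toy_mutations):
        with pytest.raises(ValueError):
            compute_tmb(toy_mutations, capture_size_mb=0)


class TestTopMutatedGenes:
    def test_ordering_and_tie_break(self):
        samples = ["s1", "s2", "s3", "s4", "s5", "s1", "s2", "s3", "s1", "s2", "s3"]
        genes = ["X"] * 5 + ["Y"] * 3 + ["Z"] * 3
        table = top_mutated_genes(_table(samples, genes))
        assert table["gene"].tolist() == ["X", "Y", "Z"]  # tie Y/Z -> alphabetical
        assert table["n_mutated"].tolist() == [5, 3, 3]

    def test_n_one(self):
        table = top_mutated_genes(_table(["s1", "s2", "s1"], ["X", "X", "Y"]), n=1)
        assert table["gene"].tolist() == ["X"]

    def test_n_larger_than_genes_gives_full_list(self):
        table = top_mutated_genes(_table(["s1"], ["X"]), n=10)
        assert len(table) == 1


class TestSomaticInteractions:
    def test_perfect_cooccurrence(self):
        # 10 samples with both A and B mutated, 10 with neither
        samples = [f"s{i}" for i in range(10)] * 2 + [f"t{i}" for i in range(10)]
        genes = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        res = somatic_interactions(_table(samples, genes), ["A", "B"], sample_ids=[f"s{i}" for i in range(10)] + [f"t{i}" for i in range(10)])
        row = res.table.iloc[0]
        # p by hypergeometric enumeration: both=10 of margins 10/10 in 20
        p_expected = sum(
            p for p in (hypergeom.pmf(k, 20, 10, 10) for k in range(11)) if p <= hypergeom.pmf(10, 20, 10, 10) + 1e-12
        )
        assert row["label"] == "co-occurring"
        assert row["p"] == pytest.approx(p_expected, rel=1e-9)

    def test_perfect_exclusivity(self):
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        genes = ["A"] * 10 + ["B"] * 10
        res = somatic_interactions(_table(samples, genes), ["A", "B"])
        assert res.table.iloc[0]["label"] == "exclusive"
        assert res.table.iloc[0]["odds_ratio"] == 0.0

    def test_pair_order_swap_invariance(self):
        rng = np.random.default_rng(9)
        samples, genes = [], []
        for i in range(60):
            if rng.random() < 0.4:
                samples.append(f"s{i}"); genes.append("A")
            if rng.random() < 0.3:
                samples.append(f"s{i}"); genes.append("B")
        ids = [f"s{i}" for i in range(60)]
        ab = somatic_interactions(_table(samples, genes), ["A", "B"], sample_ids=ids).table.iloc[0]
        ba = somatic_interactions(_table(samples, genes), ["B", "A"], sample_ids=ids).table.iloc[0]
        # swapping the pair transposes the 2x2 table: p, OR, and label unchanged
        assert ab["p"] == pytest.approx(ba["p"], rel=1e-9)
        assert ab["label"] == ba["label"]
        if np.isfinite(ab["odds_ratio"]):
            assert ba["odds_ratio"] == pytest.approx(ab["odds_ratio"], rel=1e-9)
        assert (ab["both"], ab["only_a"], ab["only_b"]) == (ba["both"], ba["only_b"], ba["only_a"])

    def test_absent_gene_labelled_none(self):
        res = somatic_interactions(_table(["s1"], ["A"]), ["A", "ZZZ"], sample_ids=["s1", "s2"])
        assert res.table.iloc[0]["label"] == "none"


class TestInferSubclones:
    def test_point_mass_single_cluster(self):
        mut = _table([f"s"] * 20, [f"G{i}" for i in range(20)], ref=[50] * 20, alt=[50] * 20)
        res = infer_subclones(mut, "s", seed=0)
        assert res.evaluable
        assert res.n_subclones == 1
        assert res.cluster_means[0] == pytest.approx(0.5, abs=1e-6)

    def test_too_few_variants_not_evaluable(self):
        mut = _table(["s"] * 5, [f"G{i}" for i in range(5)])
        res = infer_subclones(mut, "s", min_vaf_count=10)
        assert not res.evaluable
        assert res.n_subclones is None

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(12)
        depth = 100
        alts = np.concatenate([rng.binomial(depth, 0.45, 25), rng.binomial(depth, 0.10, 25)])
        mut = _table(["s"] * 50, [f"G{i}" for i in range(50)], ref=(depth - alts).tolist(), alt=alts.tolist())
        res = infer_subclones(mut, "s", seed=1)
        assert res.n_subclones == 2
        assert res.cluster_means[0] == pytest.approx(0.45, abs=0.05)
        assert res.cluster_means[1] == pytest.approx(0.10, abs=0.05)
        assert res.clonal_cluster == 0  # highest-VAF cluster flagged clonal

    def test_bic_trace_recorded(self):
        rng = np.random.default_rng(2)
        alts = rng.binomial(100, 0.4, 30)
        mut = _table(["s"] * 30, [f"G{i}" for i in range(30)], ref=(100 - alts).tolist(), alt=alts.tolist())
        res = infer_subclones(mut, "s", k_max=3, seed=3)
        assert set(res.bic_trace) == {1, 2, 3}


class TestSelectDriverGenes:
    def test_frequency_rule(self):
        samples = [f"s{i}" for i in range(20)]
        genes = ["FREQ"] * 20
        rare = _table(samples + ["s0", "s1"], genes + ["RARE", "RARE"])
        ids = [f"s{i}" for i in range(200)]
        out = select_driver_genes(rare, min_fraction=0.05, min_samples=5, sample_ids=ids)
        assert out == ["FREQ"]  # 20/200 = 10% selected; RARE in 2 excluded

    def test_empty_table(self):
        empty = MutationTable(pd.DataFrame(columns=["sample_id", "gene", "variant_classification", "chrom", "position", "ref_count", "alt_count"]))
        assert select_driver_genes(empty) == []
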