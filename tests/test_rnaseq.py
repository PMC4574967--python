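"""FPKM, dispersion shrinkage, NB exact test, BH, cascade, k-means."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meiowave import rnaseq
from meiowave.rnaseq import (
    FilterConfig,
    bh_adjust,
    compute_fpkm,
    estimate_dispersions,
    exact_nb_test,
    filter_cascade,
    kmeans_pearson,
    simulate_profile_matrix,
    spacetime_correlation,
)


class TestFpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s1": [200, 0]}, index=["a", "b"])
        lengths = pd.Series([1000, 500], index=["a", "b"])
        libs = pd.Series([20e6], index=["s1"])
        fpkm = compute_fpkm(counts, lengths, libs)
        assert fpkm.loc["a", "s1"] == pytest.approx(10.0)
        assert fpkm.loc["b", "s1"] == 0.0

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series([100], index=["a"]),
                         pd.Series([0.0], index=["s1"]))


class TestDispersions:
    @staticmethod
    def _groups(cols, n_a):
        return pd.Series(["A"] * n_a + ["B"] * (len(cols) - n_a), index=cols)

    def test_zero_variance_counts_give_zero_dispersion(self):
        counts = pd.DataFrame(np.tile([[50], [20]], (1, 6)))
        disp = estimate_dispersions(counts, self._groups(counts.columns, 3))
        assert np.allclose(disp, 0.0)

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(100.0, size=(1000, 6)))
        disp = estimate_dispersions(counts, self._groups(counts.columns, 3))
        assert float(np.median(disp)) < 0.05

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_nb_truth_recovered_within_band(self, seed):
        rng = np.random.default_rng(seed)
        r = 1 / 0.2
        counts = pd.DataFrame(rng.poisson(rng.gamma(r, 100 / r, size=(1000, 8))))
        disp = estimate_dispersions(counts, self._groups(counts.columns, 4))
        assert 0.1 <= float(disp.mean()) <= 0.3

    def test_all_zero_gene_gets_common_dispersion(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50.0, size=(50, 6)))
        counts.iloc[0] = 0
        disp = estimate_dispersions(counts, self._groups(counts.columns, 3))
        assert disp.iloc[0] >= 0.0
        assert np.isfinite(disp.iloc[0])


def binom_oracle(a_total, n_total, p_success):
    """Independent conditional-binomial enumeration of the two-sided p."""
    k = np.arange(n_total + 1)
    pmf = stats.binom.pmf(k, n_total, p_success)
    return float(pmf[pmf <= pmf[a_total] * (1 + 1e-10)].sum())


class TestExactTest:
    def test_symmetric_null_gives_p_one(self):
        p, lfc = exact_nb_test(np.array([10, 10, 10]), np.array([10, 10, 10]), 0.0)
        assert p == pytest.approx(1.0)
        assert lfc == pytest.approx(0.0, abs=1e-9)

    def test_three_vs_zero_matches_hand_enumeration(self):
        # Binomial(3, 1/2): outcomes {0, 3} are no more probable than observed
        p, lfc = exact_nb_test(np.array([3]), np.array([0]), 0.0)
        assert p == pytest.approx(0.25, abs=1e-12)
        assert lfc > 0

    def test_large_separation_is_overwhelming(self):
        p, _ = exact_nb_test(np.array([100]), np.array([0]), 0.0)
        assert p < 1e-20

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(np.array([1]), np.array([1]), -0.1)

    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 2), (3, 3), (2, 3)])
    def test_poisson_limit_matches_binomial_oracle(self, n_a, n_b):
        """At phi=0 the conditional law is binomial; enumerate all totals <=12."""
        for total in range(1, 13):
            for a in range(total + 1):
                counts_a = np.zeros(n_a)
                counts_a[0] = a
                counts_b = np.zeros(n_b)
                counts_b[0] = total - a
                p, _ = exact_nb_test(counts_a, counts_b, 0.0)
                expected = binom_oracle(a, total, n_a / (n_a + n_b))
                assert p == pytest.approx(expected, abs=1e-12)

    def test_dispersion_widens_the_null(self):
        a, b = np.array([30, 28, 35]), np.array([18, 15, 20])
        p0, _ = exact_nb_test(a, b, 0.0)
        p1, _ = exact_nb_test(a, b, 0.3)
        assert p1 > p0


def bh_reference(p):
    """Hand step-up: q_(i) = min over j>=i of p_(j) * n / j."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    n = len(p)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = running
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_capped(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_independent_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_reference(p), atol=1e-12)


class TestFilterCascade:
    def test_fixture_reproduces_hand_enumeration(self, fixture_de):
        fpkm, meta, de, config = fixture_de
        report = filter_cascade(fpkm, meta, de, config)
        assert report.stage1_expressed == {"GeneA", "GeneC", "GeneD", "GeneE",
                                           "GeneG", "GeneH", "Rec8"}
        assert report.stage2_germcell == {"GeneA", "GeneD", "GeneE", "GeneG",
                                          "GeneH"}
        assert set(report.include_list) == {"Rec8"}
        assert report.stage3_ovary_enriched == {"GeneA", "GeneE", "GeneG",
                                                "GeneH", "Rec8"}
        assert report.stage4_upregulated == {"GeneA", "GeneG", "GeneH", "Rec8"}
        assert report.counts["stage4_upregulated"] == 4

    def test_nothing_past_stage1_without_expression(self, fixture_de):
        fpkm, meta, de, config = fixture_de
        import dataclasses
        strict = dataclasses.replace(config, fpkm_min=1e6, include_list=())
        report = filter_cascade(fpkm, meta, de, strict)
        assert not report.stage1_expressed
        assert not report.stage4_upregulated

    def test_tightening_thresholds_never_enlarges_stages(self, fixture_de):
        fpkm, meta, de, config = fixture_de
        import dataclasses
        base = filter_cascade(fpkm, meta, de, config)
        for change in ({"fpkm_min": 15.0}, {"fc_min": 6.0}, {"q_max": 1e-6}):
            tight = filter_cascade(fpkm, meta, de,
                                   dataclasses.replace(config, **change))
            assert tight.stage1_expressed <= base.stage1_expressed
            assert tight.stage2_germcell <= base.stage2_germcell
            assert tight.stage3_ovary_enriched <= base.stage3_ovary_enriched
            assert tight.stage4_upregulated <= base.stage4_upregulated

    def test_missing_contrast_rejected(self, fixture_de):
        fpkm, meta, de, config = fixture_de
        with pytest.raises(KeyError):
            filter_cascade(fpkm, meta, {k: v for k, v in de.items() if k != "s3"},
                           config)

    def test_nested_stage_sets(self, fixture_de):
        fpkm, meta, de, config = fixture_de
        report = filter_cascade(fpkm, meta, de, config)
        stage2_plus = report.stage2_germcell | set(report.include_list)
        assert report.stage4_upregulated <= report.stage3_ovary_enriched
        assert report.stage3_ovary_enriched <= stage2_plus
        assert stage2_plus <= report.stage1_expressed


class TestKmeansPearson:
    def test_identical_row_groups_form_pure_clusters(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 4))
        x = np.repeat(base, 6, axis=0)
        labels, const = kmeans_pearson(x, k=5, restarts=10, seed=1)
        assert not const.any()
        frame = pd.DataFrame({"planted": np.repeat(np.arange(5), 6),
                              "got": labels})
        assert (frame.groupby("planted")["got"].nunique() == 1).all()
        assert frame["got"].nunique() == 5

    def test_positive_scaling_leaves_assignment_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 4))
        a, _ = kmeans_pearson(x, k=3, restarts=5, seed=2)
        scaled = x * rng.uniform(0.5, 5.0, size=(30, 1))
        b, _ = kmeans_pearson(scaled, k=3, restarts=5, seed=2)
        assert np.array_equal(a, b)

    def test_planted_profiles_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        mat, planted = simulate_profile_matrix(seed=0)
        labels, const = kmeans_pearson(mat, k=5, restarts=20, seed=0)
        assert adjusted_rand_score(planted, labels) >= 0.9
        assert const.sum() == 40  # the flat class

    def test_needs_enough_rows(self):
        with pytest.raises(ValueError):
            kmeans_pearson(np.zeros((3, 4)), k=5)


class TestSpacetimeCorrelation:
    def test_identity_and_antisymmetry(self):
        v = np.array([1.0, -0.5, 2.0, 0.3])
        assert spacetime_correlation(v, v) == pytest.approx(1.0)
        assert spacetime_correlation(v, -v) == pytest.approx(-1.0)

    def test_needs_three_genes(self):
        with pytest.raises(ValueError):
            spacetime_correlation([1, 2], [1, 2])


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the cross-check oracle")
def test_exact_test_agrees_with_edger_oracle(tmp_path):
    """Independent cross-check: edgeR's exact test on the same counts.

    The conditioning schemes differ in detail (quantile-adjusted pseudo-counts
    there, rounded common-scale totals here), so agreement is checked on the
    ranking and overall scale of the evidence, not bit-exactly.
    """
    rng = np.random.default_rng(123)
    n_genes = 150
    lam = np.full((n_genes, 6), 100.0)
    lam[:30, :3] *= 3.0
    r = 1 / 0.1
    counts = pd.DataFrame(rng.poisson(rng.gamma(r, lam / r)),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(6)])
    counts_path = tmp_path / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    script = tmp_path / "edger.R"
    script.write_text(f"""
suppressMessages(library(edgeR))
x <- as.matrix(read.delim("{counts_path}", row.names = 1))
group <- factor(c("A","A","A","B","B","B"))
y <- DGEList(counts = x, group = group)
y <- calcNormFactors(y)
y <- estimateCommonDisp(y)
y <- estimateTagwiseDisp(y)
et <- exactTest(y, pair = c("B","A"))
write.table(data.frame(gene = rownames(et$table), p = et$table$PValue),
            "{tmp_path / 'edger_p.tsv'}", sep = "\t", row.names = FALSE,
            quote = FALSE)
""")
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert res.returncode == 0, res.stderr
    edger = pd.read_csv(tmp_path / "edger_p.tsv", sep="\t").set_index("gene")["p"]

    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    disp = estimate_dispersions(counts, groups)
    ours = pd.Series(
        [exact_nb_test(counts.iloc[i, :3].to_numpy(),
                       counts.iloc[i, 3:].to_numpy(), float(disp.iloc[i]))[0]
         for i in range(n_genes)],
        index=counts.index,
    )
    edger = edger.loc[ours.index]
    # evidence agrees on the log scale overall, and in rank where there is
    # signal (null-gene ranks are noise in both methods, as they should be)
    log_corr = stats.pearsonr(np.log10(ours + 1e-300),
                              np.log10(edger + 1e-300)).statistic
    assert log_corr > 0.9
    planted = ours.index[:30]
    assert stats.spearmanr(ours[planted], edger[planted]).statistic > 0.9
    # both routes recover the great majority of the planted 3-fold genes
    ours_sig = set(ours.index[bh_adjust(ours) < 0.01])
    edger_sig = set(edger.index[bh_adjust(edger) < 0.01])
    assert len(ours_sig & set(planted)) >= 21
    assert len(edger_sig & set(planted)) >= 21
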