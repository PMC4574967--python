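"""Stra8-dependency class calls and single-cell correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meiowave.classify import (
    QUARTILE_LABELS,
    ReplicateSummary,
    classify_gene,
    quartile_partition,
    replicate_means,
    spearman_by_replicate,
)
from meiowave.simulate import density, simulate_ovary, simulate_replicates


def make_cells(densities_by_rep, gene="g", genotype="wildtype", age=14.5):
    rows = []
    for rep, dens in densities_by_rep.items():
        for i, d in enumerate(dens):
            rows.append({
                "cell_id": f"{rep}_c{i}", "replicate_id": rep,
                "genotype": genotype, "tissue": "ovary", "age": age,
                "ap_position": (i + 0.5) / len(dens), "volume": 1.0,
                "ra_factor": 1.0, gene: float(d),
            })
    return pd.DataFrame(rows)


def summaries(gene, genotype, means, n_cells=300, per_cell=None):
    """Hand-built replicate summaries (density scale: 1e-3 transcripts/um^3)."""
    out = []
    for i, m in enumerate(means):
        out.append(ReplicateSummary(
            gene=gene, genotype=genotype, age=14.5, replicate_id=f"r{i}",
            mean_density=float(m) * 1e-3,
            mean_transcripts=float(m) * 0.5 if per_cell is None else per_cell,
            n_cells=n_cells,
        ))
    return out


class TestReplicateMeans:
    def test_arithmetic_mean_of_densities(self):
        cells = make_cells({"r0": [1.0, 2.0, 3.0]})
        (s,) = replicate_means(cells, "g")
        assert s.mean_density == pytest.approx(2.0)
        assert s.mean_transcripts == pytest.approx(2.0)
        assert s.n_cells == 3

    def test_identical_replicates_identical_means(self):
        cells = make_cells({"r0": [1, 5, 9], "r1": [1, 5, 9]})
        a, b = replicate_means(cells, "g")
        assert a.mean_density == b.mean_density

    def test_simulated_means_near_generative_mean(self, params):
        cells = simulate_replicates("wildtype", 14.5, params, master_seed=4,
                                    n_replicates=3)
        from meiowave.simulate import mean_density
        gene = params.gene("Sycp3")
        expected = np.mean([mean_density(gene, "wildtype", 14.5, u, 1.0, params)
                            for u in np.linspace(0, 1, 101)])
        got = [s.mean_density for s in replicate_means(cells, "Sycp3")]
        se = np.std(got, ddof=1) / np.sqrt(len(got))
        assert abs(np.mean(got) - expected) < 3 * max(se, 1e-4)


class TestClassifyGene:
    def test_planted_class2_pattern_recovered(self):
        """wt 10, Stra8-null 4, Dazl-null 0.2 (x1e-3 /um^3), 3 replicates."""
        hits = 0
        for seed in range(1, 51):
            rng = np.random.default_rng(seed)
            call = classify_gene(
                summaries("g", "wildtype", 10 + 0.5 * rng.normal(size=3)),
                summaries("g", "stra8_null", 4 + 0.3 * rng.normal(size=3)),
                summaries("g", "dazl_null", 0.2 + 0.05 * rng.normal(size=3),
                          per_cell=0.1),
            )
            hits += call.class_label == "class2"
        assert hits >= 48  # >= 95% of 50 runs

    def test_identical_distributions_unclassified(self):
        call = classify_gene(summaries("g", "wildtype", [5, 5.1, 4.9]),
                             summaries("g", "stra8_null", [5, 5.1, 4.9]),
                             summaries("g", "dazl_null", [5, 5.1, 4.9]))
        assert call.class_label == "unclassified"

    def test_low_expression_guard_skips_mutant_contrast(self):
        call = classify_gene(
            summaries("g", "wildtype", [10, 11, 9]),
            summaries("g", "stra8_null", [0.5, 0.6, 0.4], per_cell=0.3),
            summaries("g", "dazl_null", [0.1, 0.2, 0.15], per_cell=0.08),
        )
        assert call.class_label == "low_expression"
        assert np.isnan(call.p_stra8_vs_dazl)

    def test_elevated_in_stra8_null_flagged_class1(self):
        call = classify_gene(summaries("g", "wildtype", [8, 8.2, 7.8]),
                             summaries("g", "stra8_null", [11, 11.3, 10.7]),
                             summaries("g", "dazl_null", [0.2, 0.25, 0.15],
                                       per_cell=0.1))
        assert call.class_label == "class1"
        assert "elevated_in_stra8_null" in call.direction_flags

    def test_requires_two_replicates_per_genotype(self):
        with pytest.raises(ValueError):
            classify_gene(summaries("g", "wildtype", [5]),
                          summaries("g", "stra8_null", [4, 4]),
                          summaries("g", "dazl_null", [1, 1]))

    def test_decision_table_is_total(self):
        """Every combination of group mean levels maps to exactly one label."""
        labels = {"class1", "class2", "class3", "low_expression", "unclassified"}
        levels = [0.2, 4.0, 10.0]
        for wt, s8, dz in itertools.product(levels, repeat=3):
            call = classify_gene(
                summaries("g", "wildtype", wt + np.array([0, 0.02, -0.02])),
                summaries("g", "stra8_null", s8 + np.array([0, 0.02, -0.02]),
                          per_cell=s8 * 0.5),
                summaries("g", "dazl_null", dz + np.array([0, 0.02, -0.02]),
                          per_cell=dz * 0.5),
            )
            assert call.class_label in labels


class TestSpearman:
    def test_perfect_monotone_gives_unit_rho(self):
        cells = make_cells({"r0": [1, 2, 3, 4, 5]})
        cells["h"] = cells["g"] ** 2
        (res,) = spearman_by_replicate(cells, "g", "h")
        assert res.rho == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 50), min_size=5, max_size=30, unique=True),
           st.sampled_from(["square", "log", "affine"]))
    def test_invariant_under_strictly_monotone_transforms(self, vals, fn):
        rng = np.random.default_rng(0)
        other = rng.permutation(len(vals)).astype(float) + 1
        cells = make_cells({"r0": vals})
        cells["h"] = other
        base = spearman_by_replicate(cells, "g", "h")[0].rho
        transform = {"square": lambda x: x ** 2, "log": np.log,
                     "affine": lambda x: 3 * x + 1}[fn]
        cells["g"] = transform(cells["g"])
        assert spearman_by_replicate(cells, "g", "h")[0].rho \
            == pytest.approx(base, abs=1e-12)

    def test_independent_genes_center_on_zero(self, params):
        """With no shared RA factor the panel genes decouple."""
        import dataclasses
        quiet = dataclasses.replace(params, ra_sigma=0.0)
        rhos = []
        for seed in range(20):
            cells = simulate_ovary("dazl_null", 14.5, quiet, seed=seed,
                                   n_cells=150)
            rhos.append(stats.spearmanr(cells["Sycp3"] / cells["volume"],
                                        cells["Dmc1"] / cells["volume"]).statistic)
        assert abs(np.mean(rhos)) < 0.1

    def test_class2_tracks_rec8_in_stra8_null(self, params):
        cells = simulate_replicates("stra8_null", 14.5, params, master_seed=8,
                                    n_replicates=3)
        for res in spearman_by_replicate(cells, "Sycp3", "Rec8"):
            assert res.rho > 0

    def test_rejects_tiny_replicates(self):
        cells = make_cells({"r0": [1, 2]})
        cells["h"] = [2.0, 1.0]
        with pytest.raises(ValueError):
            spearman_by_replicate(cells, "g", "h")


class TestQuartilePartition:
    def test_evenly_spaced_cells_split_two_per_bin(self):
        cells = make_cells({"r0": np.ones(8)})
        cells["ap_position"] = np.arange(1, 16, 2) / 16
        bins = quartile_partition(cells)
        assert [len(bins[k]) for k in QUARTILE_LABELS] == [2, 2, 2, 2]

    def test_boundary_cell_goes_to_upper_bin(self):
        cells = make_cells({"r0": [1.0]})
        cells["ap_position"] = [0.25]
        bins = quartile_partition(cells)
        assert len(bins["mid_posterior"]) == 1
        assert len(bins["posteriormost"]) == 0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_partition_conserves_cells(self, positions):
        cells = make_cells({"r0": np.ones(len(positions))})
        cells["ap_position"] = positions
        bins = quartile_partition(cells)
        assert sum(len(b) for b in bins.values()) == len(cells)
        recovered = pd.concat(bins.values()).sort_index()
        assert list(recovered.index) == list(cells.index)
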