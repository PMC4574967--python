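"""Simulation-based validation of the full pipeline.

Each routine here generates data under known (planted) conditions with the
package's own generator, runs the corresponding analysis end to end, and
returns the measured performance: error-rate calibration of the exact test,
recovery of planted regulatory classes and registration offsets, and the
qualitative regulatory signatures (induction ordering, Stra8-dependent
down-regulation, quartile-resolved correlation reversal, RA refractoriness).
All randomness flows from explicit seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from . import rnaseq
from .classify import classify_panel, quartile_partition
from .simulate import (
    SMFISH_PANEL,
    SimulationParams,
    default_params,
    density,
    expected_class_call,
    simulate_ovary,
    simulate_replicates,
)
from .trace import Trace, build_joined_trace, half_max_time, register_traces, \
    windowed_trace

EARLY_GENES = ("Rec8", "Stag3", "Smc1b", "Gm1564")
CLASS3_GENES = ("Dmc1", "Hormad1", "M1ap", "Mei1", "Msh5")


def exact_test_oracle_max_error(max_total: int = 12) -> float:
    """Largest |p - oracle| over all Poisson-limit conditional tests.

    The oracle is a direct enumeration of the conditional binomial law.
    """
    worst = 0.0
    for n_a, n_b in ((1, 1), (2, 2), (3, 3), (2, 3)):
        share = n_a / (n_a + n_b)
        for total in range(1, max_total + 1):
            k = np.arange(total + 1)
            pmf = stats.binom.pmf(k, total, share)
            for a in range(total + 1):
                counts_a = np.zeros(n_a)
                counts_a[0] = a
                counts_b = np.zeros(n_b)
                counts_b[0] = total - a
                p, _ = rnaseq.exact_nb_test(counts_a, counts_b, 0.0)
                oracle = float(pmf[pmf <= pmf[a] * (1 + 1e-10)].sum())
                worst = max(worst, abs(p - oracle))
    return worst


def _null_counts(seed: int, n_genes: int, phi: float, mu: float,
                 n_per_group: int = 3) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    shape = (n_genes, 2 * n_per_group)
    if phi == 0:
        counts = rng.poisson(mu, size=shape)
    else:
        r = 1 / phi
        counts = rng.poisson(rng.gamma(r, mu / r, size=shape))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)])


def _pipeline_pvalues(counts: pd.DataFrame, n_a: int) -> np.ndarray:
    groups = pd.Series(["A"] * n_a + ["B"] * (counts.shape[1] - n_a),
                       index=counts.columns)
    disp = rnaseq.estimate_dispersions(counts, groups)
    return np.array([
        rnaseq.exact_nb_test(counts.iloc[i, :n_a].to_numpy(),
                             counts.iloc[i, n_a:].to_numpy(),
                             float(disp.iloc[i]))[0]
        for i in range(len(counts))
    ])


def null_rejection_rate(seed: int, n_genes: int = 2000, phi: float = 0.1,
                        mu: float = 100.0, alpha: float = 0.05) -> float:
    """Type-I error of the exact test with estimated tagwise dispersions."""
    p = _pipeline_pvalues(_null_counts(seed, n_genes, phi, mu), 3)
    return float((p < alpha).mean())


def empirical_fdr(seeds, n_genes: int = 2000, phi: float = 0.1,
                  mu: float = 100.0, effect: float = 4.0,
                  de_fraction: float = 0.1, q_max: float = 0.01):
    """Mean false-discovery proportion and power at q < q_max, with 4-fold
    effects planted in a fraction of genes."""
    fdrs, powers = [], []
    n_de = int(de_fraction * n_genes)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        lam = np.full((n_genes, 6), mu)
        lam[:n_de, :3] *= effect
        r = 1 / phi
        counts = pd.DataFrame(rng.poisson(rng.gamma(r, lam / r)),
                              index=[f"g{i}" for i in range(n_genes)])
        q = rnaseq.bh_adjust(_pipeline_pvalues(counts, 3))
        sig = q < q_max
        is_de = np.zeros(n_genes, bool)
        is_de[:n_de] = True
        fdrs.append(float((sig & ~is_de).sum() / max(sig.sum(), 1)))
        powers.append(float(sig[is_de].mean()))
    return float(np.mean(fdrs)), float(np.mean(powers))


def registration_recovery_max_error(seeds, noise: float = 0.01,
                                    ages=None, span: float = 2.0,
                                    flat_tol: float = 0.05) -> float:
    """Largest per-pair shift error when registering traces that were
    translated by known offsets (the age-to-position mapping of the wave).

    ``noise`` is the observation noise of a trace value relative to a
    unit-scale profile; 0.01 corresponds to the standard error of a windowed
    mean at the default cells-per-ovary.  ``flat_tol`` is matched to that
    noise level (the default pipeline guard is sized for noisier smFISH
    traces).
    """
    params = default_params()
    if ages is None:
        ages = params.ages
    true_offsets = np.diff(np.asarray(ages)) / span
    centers = np.linspace(0, 1, 100)
    worst = 0.0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        # ramp plus mild oscillation: informative slope everywhere, so every
        # age pair constrains its offset (no flat plateaus)
        slope = rng.uniform(0.8, 1.2)
        wiggle = rng.uniform(0.2, 0.3)
        phase = rng.uniform(0, 2 * np.pi)

        def profile(x):
            return slope * x + wiggle * np.sin(2.2 * x + phase)

        shift = 0.0
        traces = {}
        for i, age in enumerate(ages):
            if i > 0:
                shift += true_offsets[i - 1]
            vals = profile(centers + shift) + rng.normal(0, noise, centers.size)
            traces[age] = Trace(gene="Stra8", genotype="wildtype", age=age,
                                window_centers=centers, mean_density=vals,
                                sd_density=np.zeros_like(vals),
                                n_cells=np.full(centers.size, 50))
        axis = register_traces(traces, flat_tol=flat_tol)
        got = np.diff(axis.shifts)
        worst = max(worst, float(np.max(np.abs(got - true_offsets))))
    return worst


def class_recovery(seeds, params: SimulationParams | None = None,
                   n_replicates: int = 3, n_cells: int = 300):
    """Fraction of seeded runs recovering >=12 of the 13 smFISH-panel genes'
    expected class calls, plus how often Rec8 carries the elevation flag."""
    if params is None:
        params = default_params()
    expected = {g.name: expected_class_call(g, params)
                for g in params.gene_panel if g.name in SMFISH_PANEL}
    good_runs = 0
    rec8_flagged = 0
    per_run_correct = []
    for seed in seeds:
        tables = [
            simulate_replicates(gt, 14.5, params, master_seed=1000 * seed + k,
                                n_replicates=n_replicates, n_cells=n_cells)
            for k, gt in enumerate(("wildtype", "stra8_null", "dazl_null"))
        ]
        cells = pd.concat(tables, ignore_index=True)
        calls = classify_panel(cells, genes=list(SMFISH_PANEL))
        calls = calls.set_index("gene")
        n_correct = sum(calls.loc[g, "class"] == expected[g]
                        for g in SMFISH_PANEL)
        per_run_correct.append(n_correct)
        good_runs += n_correct >= 12
        rec8_flagged += "elevated_in_stra8_null" in calls.loc["Rec8",
                                                              "direction_flags"]
    n = len(list(seeds))
    return good_runs / n, rec8_flagged / n, per_run_correct


def _joined_traces(genotype: str, genes, params: SimulationParams, seed0: int,
                   axis=None):
    per_gene = {}
    cells_by_age = {
        age: simulate_ovary(genotype, age, params, seed=seed0 + i)
        for i, age in enumerate(params.ages)
    }
    if axis is None:
        ref = {age: windowed_trace(cells, "Stra8")
               for age, cells in cells_by_age.items()}
        axis = register_traces(ref)
    for gene in genes:
        traces = {age: windowed_trace(cells, gene)
                  for age, cells in cells_by_age.items()}
        per_gene[gene] = build_joined_trace(traces, axis)
    return per_gene, axis


def temporal_ordering(seed: int, params: SimulationParams | None = None,
                      tolerance: float = 0.1):
    """Half-max coordinates of the panel on the wild-type joined axis.

    Returns (half_max dict, early_ok, class3_ok): early class-1/2 genes reach
    half-max no later than Stra8 (+tolerance); class-3 genes strictly later.
    """
    if params is None:
        params = default_params()
    genes = ("Stra8",) + EARLY_GENES + CLASS3_GENES
    joined, _ = _joined_traces("wildtype", genes, params, seed0=seed)
    hm = {g: half_max_time(joined[g]).coordinate for g in genes}
    early_ok = all(hm[g] <= hm["Stra8"] + tolerance for g in EARLY_GENES)
    class3_ok = all(hm[g] > hm["Stra8"] for g in CLASS3_GENES)
    return hm, early_ok, class3_ok


def persistence_fraction(seed: int, params: SimulationParams | None = None):
    """Stra8-null persistence of Rec8 and the Stra8-promoter reporter.

    On the wild-type-derived axis, over coordinates past the wild-type peak
    where the wild-type trace has fallen below 25% of its own maximum,
    returns per gene the fraction at which the Stra8-null trace still exceeds
    50% of its own maximum.
    """
    if params is None:
        params = default_params()
    genes = ("Rec8", "Stra8lacZ")
    wt, axis = _joined_traces("wildtype", genes, params, seed0=seed)
    null, _ = _joined_traces("stra8_null", genes, params, seed0=seed + 50,
                             axis=axis)
    out = {}
    for gene in genes:
        w, m = wt[gene], null[gene]
        wt_peak = float(np.nanmax(w.mean_density))
        null_peak = float(np.nanmax(m.mean_density))
        past_peak = np.arange(len(w.coordinates)) > int(np.nanargmax(w.mean_density))
        low = w.coordinates[past_peak & (w.mean_density < 0.25 * wt_peak)]
        vals = np.interp(low, m.coordinates, m.mean_density,
                         left=np.nan, right=np.nan)
        vals = vals[~np.isnan(vals)]
        out[gene] = float(np.mean(vals > 0.5 * null_peak)) if vals.size else np.nan
    return out


def quartile_reversal(seeds, params: SimulationParams | None = None,
                      n_cells: int = 400, alpha: float = 0.05):
    """Sycp3-Rec8 correlation by AP quarter in wild-type E14.5 ovaries.

    A seed counts as reproducing the reversal when the posteriormost quarter
    correlates positively and the anteriormost is non-positive or not
    significant.  Returns (fraction of seeds, mean posterior rho, mean
    anterior rho).
    """
    if params is None:
        params = default_params()
    ok = 0
    post_rhos, ant_rhos = [], []
    for seed in seeds:
        cells = simulate_ovary("wildtype", 14.5, params, seed=seed,
                               n_cells=n_cells)
        bins = quartile_partition(cells)
        post = bins["posteriormost"]
        ant = bins["anteriormost"]
        rp = stats.spearmanr(density(post, "Sycp3"), density(post, "Rec8"))
        ra = stats.spearmanr(density(ant, "Sycp3"), density(ant, "Rec8"))
        post_rhos.append(rp.statistic)
        ant_rhos.append(ra.statistic)
        ok += (rp.statistic > 0) and (ra.statistic <= 0 or ra.pvalue > alpha)
    n = len(list(seeds))
    return ok / n, float(np.mean(post_rhos)), float(np.mean(ant_rhos))


def kmeans_recovery(seed: int):
    """Adjusted Rand agreement of Pearson-distance k-means with the planted
    five-profile labels."""
    from sklearn.metrics import adjusted_rand_score
    mat, planted = rnaseq.simulate_profile_matrix(seed=seed)
    labels, _ = rnaseq.kmeans_pearson(mat, k=5, restarts=20, seed=seed)
    return float(adjusted_rand_score(planted, labels))


def spacetime_consistency(seed: int):
    """Correlation of per-gene expression change over time vs over space."""
    from .bulk import anterior_posterior_design, default_bulk_panel, \
        simulate_bulk_counts
    panel = default_bulk_panel()
    design = anterior_posterior_design(panel)
    params = dataclasses.replace(default_params(), gene_panel=panel)
    cm = simulate_bulk_counts(design, params, seed=seed)
    meta = cm.sample_meta

    def ids(age, lo):
        sel = (meta["age"] == age) & (meta["segment_lo"].round(2) == lo)
        return list(meta.index[sel])

    over_time = rnaseq.de_contrast(cm, ids(13.5, 0.67), ids(12.5, 0.67))
    over_space = rnaseq.de_contrast(cm, ids(13.5, 0.67), ids(13.5, 0.0))
    meio = [g.name for g in panel
            if g.reg_class in ("class1", "class2", "class3")]
    return rnaseq.spacetime_correlation(
        over_time.loc[meio, "log2_fold_change"],
        over_space.loc[meio, "log2_fold_change"])


def cascade_recovery(seed: int):
    """End-to-end filter cascade on the default synthetic bulk design.

    Returns (fraction of planted meiotic-program genes in the final set,
    fraction of planted somatic / germline-shared / pluripotency genes
    admitted, per-stage counts).
    """
    from .bulk import default_bulk_design, default_bulk_panel, \
        simulate_bulk_counts
    panel = default_bulk_panel()
    design = default_bulk_design(panel)
    params = dataclasses.replace(default_params(), gene_panel=panel)
    cm = simulate_bulk_counts(design, params, seed=seed)
    meta = cm.sample_meta
    fpkm = rnaseq.compute_fpkm(cm)

    def ids(**criteria):
        sel = pd.Series(True, index=meta.index)
        for key, val in criteria.items():
            sel &= meta[key] == val
        return list(meta.index[sel])

    de, stage2, stage4 = {}, [], []
    ages = sorted(meta.loc[meta.genotype == "wildtype", "age"].unique())
    for age in ages:
        label = f"s2_E{age}"
        de[label] = rnaseq.de_contrast(
            cm, ids(tissue="ovary", genotype="wildtype", age=age),
            ids(tissue="ovary", genotype="kit_null", age=age))
        stage2.append(label)
    mid = ages[len(ages) // 2]
    de["s3"] = rnaseq.de_contrast(
        cm, ids(tissue="ovary", genotype="wildtype", age=mid),
        ids(tissue="testis", genotype="wildtype", age=mid))
    for age in ages[1:]:
        label = f"s4_E{age}"
        de[label] = rnaseq.de_contrast(
            cm, ids(tissue="ovary", genotype="wildtype", age=age),
            ids(tissue="ovary", genotype="wildtype", age=ages[0]))
        stage4.append(label)
    config = rnaseq.FilterConfig(stage2_contrasts=tuple(stage2),
                                 stage3_contrast="s3",
                                 stage4_contrasts=tuple(stage4))
    report = rnaseq.filter_cascade(fpkm, meta, de, config)
    final = report.stage4_upregulated
    meio = {g.name for g in panel
            if g.reg_class in ("class1", "class2", "class3")
            and not g.name.startswith("Shared")}
    planted_neg = {g.name for g in panel
                   if g.name.startswith(("Soma", "Shared", "Silent"))
                   or g.reg_class == "pluripotency"}
    return (len(meio & final) / len(meio),
            len(planted_neg & final) / len(planted_neg),
            report.counts)


def ra_refractoriness(seed: int, params: SimulationParams | None = None,
                      n_cells: int = 300):
    """Stra8 response to exogenous RA at E15.5, measured at E16.5.

    Returns (ovary fold change, testis fold change): germ cells that have
    completed the Stra8 pulse are refractory; testicular germ cells respond.
    """
    if params is None:
        params = default_params()
    pulsed = dataclasses.replace(params, ra_pulse_age=15.5)

    def mean_dens(p, tissue, s):
        cells = simulate_ovary("wildtype", 16.5, p, seed=s, n_cells=n_cells,
                               tissue=tissue)
        return float(density(cells, "Stra8").mean())

    ovary = mean_dens(pulsed, "ovary", seed) / mean_dens(params, "ovary", seed)
    testis = mean_dens(pulsed, "testis", seed + 1) \
        / mean_dens(params, "testis", seed + 1)
    return ovary, testis


def dazl_dependence(seed: int, params: SimulationParams | None = None,
                    alpha: float = 0.05):
    """Fraction of meiotic panel genes significantly reduced in Dazl-null
    germ cells relative to wild type (replicate-level t-test)."""
    if params is None:
        params = default_params()
    tables = [
        simulate_replicates(gt, 14.5, params, master_seed=seed + k,
                            n_replicates=3)
        for k, gt in enumerate(("wildtype", "stra8_null", "dazl_null"))
    ]
    cells = pd.concat(tables, ignore_index=True)
    calls = classify_panel(cells, genes=list(SMFISH_PANEL)).set_index("gene")
    reduced = (calls["p_wt_vs_dazl"] < alpha).sum()
    return reduced / len(SMFISH_PANEL)
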