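"""Bulk RNA-seq analysis: FPKM, NB exact test, FDR, filter cascade, clustering.

The meiotic-prophase gene set is carved out of a whole-gonad count matrix by
four successive filters:

1. expressed in wild-type fetal ovary (>5 FPKM at any assayed age);
2. germ-cell-dependent: higher in wild-type than in germ-cell-depleted
   (Kit-mutant) ovary (fold-change > 2, q < 0.01, at any age), with a manual
   include list for genes, like Rec8, that are germ-cell-expressed but not
   germ-cell-enriched;
3. ovary-enriched: higher in fetal ovary than fetal testis (FC > 2, q < 0.01);
4. up-regulated over developmental time in the ovary (FC > 2, q < 0.01
   between the earliest and either later age).

Differential expression uses a conditional negative-binomial exact test on
group totals after scaling samples to a common effective library size, with
per-gene method-of-moments dispersions shrunk toward the common dispersion,
and Benjamini-Hochberg FDR adjustment.  Expression profiles are grouped by
k-means under the Pearson-correlation distance (1 - r) on log-transformed,
mean-centered FPKM rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "FilterConfig",
    "FilterReport",
    "compute_fpkm",
    "tmm_factors",
    "effective_library_sizes",
    "estimate_dispersions",
    "exact_nb_test",
    "de_contrast",
    "bh_adjust",
    "filter_cascade",
    "kmeans_pearson",
    "spacetime_correlation",
    "simulate_profile_matrix",
]


@dataclass
class CountMatrix:
    """Integer gene x sample counts with sample design and gene lengths."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    sample_meta: pd.DataFrame  # indexed by sample id: tissue, genotype, age, replicate
    gene_lengths: pd.Series  # bp
    library_sizes: pd.Series | None = None  # total mapped reads; else column sums

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        self.gene_lengths = self.gene_lengths.loc[self.counts.index]
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def compute_fpkm(
    counts: pd.DataFrame | CountMatrix,
    gene_lengths: pd.Series | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM = count / (gene_length_kb * library_size_millions)``.
    """
    if isinstance(counts, CountMatrix):
        gene_lengths = counts.gene_lengths
        library_sizes = counts.library_sizes
        counts = counts.counts
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("zero library size")
    len_kb = gene_lengths.loc[counts.index].to_numpy(dtype=float) / 1e3
    lib_m = library_sizes.loc[counts.columns].to_numpy(dtype=float) / 1e6
    return counts / (len_kb[:, None] * lib_m[None, :])


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    trim: float = 0.3,
) -> pd.Series:
    """Trimmed-mean-of-log-ratios scale factors (library-complexity correction).

    Each sample's per-read abundance profile is compared to the geometric-mean
    reference profile over genes detected in every sample; the central
    ``1 - 2*trim`` of log-ratios is averaged.  Factors are normalized to
    geometric mean 1.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    x = counts.to_numpy(dtype=float) / library_sizes.to_numpy(dtype=float)[None, :]
    ok = (x > 0).all(axis=1)
    if ok.sum() < 10:  # too few shared genes to normalize on
        return pd.Series(1.0, index=counts.columns)
    logx = np.log(x[ok])
    ref = logx.mean(axis=1)
    logratio = logx - ref[:, None]
    lo, hi = np.quantile(logratio, [trim, 1 - trim], axis=0)
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        sel = (logratio[:, j] >= lo[j]) & (logratio[:, j] <= hi[j])
        factors[j] = np.exp(logratio[sel, j].mean()) if sel.any() else 1.0
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def effective_library_sizes(cm: CountMatrix, trim: float = 0.3) -> pd.Series:
    return cm.library_sizes * tmm_factors(cm.counts, cm.library_sizes, trim=trim)


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    library_sizes: pd.Series | None = None,
    prior_weight: float = 10.0,
) -> pd.Series:
    """Per-gene (tagwise) NB dispersion with shrinkage toward the common value.

    Raw per-gene dispersions come from the method of moments,
    ``phi = (var - mean) / mean^2`` on counts scaled to a common library size,
    pooled over groups with replication and clamped at zero.  The common
    dispersion is a ratio-of-sums moment estimator across all genes (nearly
    unbiased at small n, unlike a median of clamped per-gene values).  Each
    raw value is then averaged with the common dispersion using
    ``prior_weight`` pseudo-samples; all-zero genes receive the common value.
    """
    groups = groups.loc[counts.columns]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    lib = library_sizes.loc[counts.columns].to_numpy(dtype=float)
    common_lib = np.exp(np.mean(np.log(lib)))
    x = counts.to_numpy(dtype=float) * (common_lib / lib)[None, :]

    dfs = np.zeros(counts.shape[0])
    num = np.zeros(counts.shape[0])
    common_num = 0.0
    common_den = 0.0
    any_group = False
    for g in groups.unique():
        sel = (groups == g).to_numpy()
        n = int(sel.sum())
        if n < 2:
            continue
        any_group = True
        m = x[:, sel].mean(axis=1)
        v = x[:, sel].var(axis=1, ddof=1)
        ok = m > 0
        phi_g = np.zeros_like(m)
        # denominator m^2 is estimated by m_hat^2 - v/n (m_hat^2 alone is
        # inflated by the sampling variance of the mean, biasing phi low)
        denom = np.maximum(m[ok] ** 2 - v[ok] / n, m[ok] ** 2 * 0.25)
        phi_g[ok] = np.maximum(0.0, (v[ok] - m[ok]) / denom)
        num += np.where(ok, (n - 1) * phi_g, 0.0)
        dfs += np.where(ok, n - 1, 0.0)
        common_num += float((v[ok] - m[ok]).sum())
        common_den += float(np.maximum(m[ok] ** 2 - v[ok] / n, 0.0).sum())
    if not any_group:
        raise ValueError("need at least one group with >=2 samples")
    with np.errstate(invalid="ignore"):
        raw = np.where(dfs > 0, num / np.maximum(dfs, 1), np.nan)
    defined = dfs > 0
    common = max(0.0, common_num / common_den) if common_den > 0 else 0.0
    shrunk = np.where(
        defined,
        (dfs * np.nan_to_num(raw) + prior_weight * common) / (dfs + prior_weight),
        common,
    )
    return pd.Series(np.maximum(shrunk, 0.0), index=counts.index, name="dispersion")


def _group_total_logpmf(k: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log P(sum of n iid NB(mu, phi) = k); Poisson when phi = 0."""
    if phi == 0:
        return stats.poisson.logpmf(k, n * mu)
    r = n / phi  # sum of n NB(mu, phi) is NB(n*mu, phi/n)
    p = r / (r + n * mu)
    return stats.nbinom.logpmf(k, r, p)


def exact_nb_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    dispersion: float,
    lib_a: np.ndarray | None = None,
    lib_b: np.ndarray | None = None,
    prior_count: float = 0.25,
) -> tuple[float, float]:
    """Two-sided conditional NB exact test for one gene.

    Samples are scaled to the common (geometric-mean) effective library size
    and summed per group.  Conditional on the grand total, the group-A total
    follows the ratio of NB group-sum pmfs; the two-sided p-value sums the
    probabilities of all outcomes no more probable than the observed one.
    Returns ``(p_value, log2_fold_change)``; the fold change uses normalized
    group means with ``prior_count`` added to each.
    """
    if dispersion < 0:
        raise ValueError("negative dispersion")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if lib_a is None:
        lib_a = np.ones(a.size)
    if lib_b is None:
        lib_b = np.ones(b.size)
    lib = np.concatenate([np.asarray(lib_a, float), np.asarray(lib_b, float)])
    common = np.exp(np.mean(np.log(lib)))
    a_scaled = a * (common / np.asarray(lib_a, float))
    b_scaled = b * (common / np.asarray(lib_b, float))
    A = int(round(a_scaled.sum()))
    B = int(round(b_scaled.sum()))
    n_a, n_b = a.size, b.size

    log2fc = float(np.log2((A / n_a + prior_count) / (B / n_b + prior_count)))

    N = A + B
    if N == 0:
        return 1.0, 0.0
    mu = N / (n_a + n_b)
    k = np.arange(N + 1)
    logp = _group_total_logpmf(k, n_a, mu, dispersion) \
        + _group_total_logpmf(N - k, n_b, mu, dispersion)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[A]
    p = float(prob[prob <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0), log2fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(
    cm: CountMatrix,
    samples_a: list[str],
    samples_b: list[str],
    dispersions: pd.Series | None = None,
    prior_weight: float = 10.0,
    prior_count: float = 0.25,
) -> pd.DataFrame:
    """Gene-wise exact-test contrast (A over B) with BH-adjusted q-values."""
    missing = (set(samples_a) | set(samples_b)) - set(cm.samples)
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(missing)}")
    eff = effective_library_sizes(cm)
    if dispersions is None:
        sub = cm.counts[list(samples_a) + list(samples_b)]
        groups = pd.Series(
            ["A"] * len(samples_a) + ["B"] * len(samples_b),
            index=sub.columns,
        )
        dispersions = estimate_dispersions(
            sub, groups, eff.loc[sub.columns], prior_weight=prior_weight)
    lib_a = eff.loc[samples_a].to_numpy()
    lib_b = eff.loc[samples_b].to_numpy()
    ca = cm.counts[samples_a].to_numpy(dtype=float)
    cb = cm.counts[samples_b].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(cm.genes):
        p, lfc = exact_nb_test(ca[i], cb[i], float(dispersions.iloc[i]),
                               lib_a, lib_b, prior_count=prior_count)
        rows.append((gene, lfc, p, float(dispersions.iloc[i])))
    out = pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p_value",
                                      "dispersion"]).set_index("gene")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


@dataclass
class FilterConfig:
    """Thresholds and contrast labels for the four-stage filter cascade."""

    fpkm_min: float = 5.0
    fc_min: float = 2.0
    q_max: float = 0.01
    include_list: tuple[str, ...] = ("Rec8",)
    stage2_contrasts: tuple[str, ...] = ()  # wt ovary vs germ-cell-depleted, per age
    stage3_contrast: str = ""  # ovary vs testis
    stage4_contrasts: tuple[str, ...] = ()  # later vs earliest age in ovary


@dataclass
class FilterReport:
    """Survivor gene sets and counts per cascade stage."""

    stage1_expressed: set
    stage2_germcell: set
    stage3_ovary_enriched: set
    stage4_upregulated: set
    include_list: dict  # gene -> reason, for genes injected manually

    @property
    def counts(self) -> dict:
        return {
            "stage1_expressed": len(self.stage1_expressed),
            "stage2_germcell": len(self.stage2_germcell),
            "stage2_plus_included": len(self.stage2_germcell)
            + len(set(self.include_list) - self.stage2_germcell),
            "stage3_ovary_enriched": len(self.stage3_ovary_enriched),
            "stage4_upregulated": len(self.stage4_upregulated),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.stage1_expressed):
            rows.append({
                "gene": gene,
                "stage1": True,
                "stage2": gene in self.stage2_germcell,
                "included_manually": gene in self.include_list,
                "stage3": gene in self.stage3_ovary_enriched,
                "stage4": gene in self.stage4_upregulated,
            })
        return pd.DataFrame(rows)


def _passes(de: pd.DataFrame, genes, fc_min: float, q_max: float) -> set:
    sub = de.loc[de.index.intersection(list(genes))]
    hit = (sub["log2_fold_change"] > np.log2(fc_min)) & (sub["q_value"] < q_max)
    return set(sub.index[hit])


def filter_cascade(
    fpkm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    de_results: dict[str, pd.DataFrame],
    config: FilterConfig,
    gene_types: pd.Series | None = None,
) -> FilterReport:
    """Apply the four-stage meiotic-prophase filter cascade.

    Stage 1 evaluates replicate-mean FPKM in wild-type ovary per age and keeps
    genes exceeding ``fpkm_min`` at any age.  Stages 2 and 4 accept a gene if
    it passes in any of their contrasts; stage 3 uses a single contrast.
    Include-list genes are injected after stage 2 (flagged manual) and must
    still pass stages 3 and 4.
    """
    for label in list(config.stage2_contrasts) + [config.stage3_contrast] \
            + list(config.stage4_contrasts):
        if label not in de_results:
            raise KeyError(f"missing contrast {label!r}")

    universe = set(fpkm.index)
    if gene_types is not None:
        coding = set(gene_types.index[gene_types == "coding"])
        universe &= coding

    wt_ovary = sample_meta[(sample_meta["genotype"] == "wildtype")
                           & (sample_meta["tissue"] == "ovary")]
    stage1 = set()
    for age, grp in wt_ovary.groupby("age"):
        means = fpkm[grp.index].mean(axis=1)
        stage1 |= set(means.index[means > config.fpkm_min])
    stage1 &= universe

    stage2 = set()
    for label in config.stage2_contrasts:
        stage2 |= _passes(de_results[label], stage1, config.fc_min, config.q_max)

    included = {g: "manual include list" for g in config.include_list
                if g in universe and g not in stage2}
    stage2_plus = stage2 | set(included)

    stage3 = _passes(de_results[config.stage3_contrast], stage2_plus,
                     config.fc_min, config.q_max)

    stage4 = set()
    for label in config.stage4_contrasts:
        stage4 |= _passes(de_results[label], stage3, config.fc_min, config.q_max)

    return FilterReport(
        stage1_expressed=stage1,
        stage2_germcell=stage2,
        stage3_ovary_enriched=stage3,
        stage4_upregulated=stage4,
        include_list=included,
    )


# ---------------------------------------------------------------------------
# k-means under Pearson-correlation distance


def _center_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def kmeans_pearson(
    profiles: pd.DataFrame | np.ndarray,
    k: int = 5,
    restarts: int = 20,
    seed: int | None = 0,
    max_iter: int = 100,
    const_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means with distance ``1 - Pearson r`` between row profiles.

    Centroids are means of member profiles, re-centered.  Rows with no
    dynamic range (undefined correlation) are flagged and assigned by a
    fallback Euclidean rule: to the nearest centroid in centered profile
    space, which for a flat row is the centroid of smallest norm.  Empty
    clusters are reseeded from the point farthest from its centroid.  The
    best of ``restarts`` seeded initializations (total within-cluster
    distance) is returned as ``(labels, constant_row_flags)``.
    """
    x = np.asarray(profiles, dtype=float)
    n, m = x.shape
    if n < k:
        raise ValueError("need at least k rows")
    if m < 2:
        raise ValueError("need at least two conditions")
    xc = _center_rows(x)
    norms = np.linalg.norm(xc, axis=1)
    const = norms < const_tol
    z = np.where(const[:, None], 0.0, xc / np.where(norms > 0, norms, 1.0)[:, None])

    rng = np.random.default_rng(seed)

    def dist_to_centroids(cents: np.ndarray) -> np.ndarray:
        """Row x centroid distance matrix under the mixed metric."""
        cnorm = np.linalg.norm(cents, axis=1)
        degenerate = cnorm < const_tol
        cz = cents / np.where(degenerate, 1.0, cnorm)[:, None]
        d = 1.0 - z @ cz.T  # 1 - Pearson for normal rows/centroids
        d[:, degenerate] = 1.0
        if const.any():
            d[const] = np.linalg.norm(
                xc[const][:, None, :] - cents[None, :, :], axis=2)
        return d

    def init_centroids() -> np.ndarray:
        # k-means++-style D^2 seeding over all rows
        first = int(rng.integers(n))
        chosen = [first]
        for _ in range(k - 1):
            d = dist_to_centroids(xc[chosen]).min(axis=1)
            d = np.maximum(d, 0.0)
            d[chosen] = 0.0
            total = d.sum()
            if total <= 0:
                cand = [i for i in range(n) if i not in chosen]
                chosen.append(int(rng.choice(cand)))
            else:
                chosen.append(int(rng.choice(n, p=d / total)))
        return xc[chosen].copy()

    best_labels, best_obj = None, np.inf
    for _restart in range(max(1, restarts)):
        cents = init_centroids()
        labels = None
        for _it in range(max_iter):
            d = dist_to_centroids(cents)
            new_labels = d.argmin(axis=1)
            # reseed empty clusters from the globally farthest point
            for c in range(k):
                if not (new_labels == c).any():
                    far = int(d[np.arange(n), new_labels].argmax())
                    cents[c] = xc[far]
                    new_labels[far] = c
            if labels is not None and (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if members.any():
                    cents[c] = _center_rows(
                        xc[members].mean(axis=0, keepdims=True))[0]
        d = dist_to_centroids(cents)
        obj = float(d[np.arange(n), labels].sum())
        if obj < best_obj:
            best_obj, best_labels = obj, labels.copy()
    return best_labels, const


def simulate_profile_matrix(
    n_per_class: int = 40,
    noise: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted five-profile matrix over three ages (log-FPKM scale).

    Shapes: pulse (up then down), sustained, late, declining, and flat.  The
    flat class has no dynamic range at all -- a profile without shape carries
    no information under correlation distance -- and exercises the
    degenerate-row pathway.  Returns ``(matrix, planted_labels)``.
    """
    shapes = {
        "pulse": np.array([0.0, 2.0, 0.0]),
        "sustained": np.array([0.0, 2.0, 2.0]),
        "late": np.array([0.0, 0.0, 2.0]),
        "declining": np.array([2.0, 1.0, 0.0]),
        "flat": np.array([1.0, 1.0, 1.0]),
    }
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for li, (name, base) in enumerate(shapes.items()):
        for _ in range(n_per_class):
            row = base.copy()
            if name != "flat":
                row = row + rng.normal(0.0, noise, size=base.size)
            rows.append(row)
            labels.append(li)
    mat = pd.DataFrame(
        np.asarray(rows), columns=["E12.5", "E14.5", "E16.5"],
        index=[f"g{i:04d}" for i in range(len(rows))],
    )
    mat = mat.sub(mat.mean(axis=1), axis=0)
    return mat, np.asarray(labels)


def spacetime_correlation(time_fc, space_fc) -> float:
    """Pearson correlation of per-gene fold changes over time vs over space."""
    t = np.asarray(time_fc, dtype=float)
    s = np.asarray(space_fc, dtype=float)
    if t.shape != s.shape:
        raise ValueError("fold-change vectors must be paired")
    if t.size < 3:
        raise ValueError("need at least 3 genes")
    return float(stats.pearsonr(t, s).statistic)
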