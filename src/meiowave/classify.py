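"""Stra8-dependency classification and single-cell correlation analysis.

A gene's dependence on *Stra8* is read out from three genotype contrasts on
per-replicate mean transcript densities (two-sample Welch t-tests at
alpha = 0.05, two-sidedness combined with the sign of the mean difference):

* class 1 -- fully Stra8-independent: not significantly lower in Stra8-null
  than in wild type, but significantly higher in Stra8-null than in Dazl-null;
* class 2 -- partially Stra8-independent: significantly lower in Stra8-null
  than wild type, yet significantly higher than Dazl-null;
* class 3 -- fully Stra8-dependent: significantly lower in Stra8-null than
  wild type, and indistinguishable from Dazl-null.

Genes whose expression in both mutants averages below one transcript per cell
are reported as ``low_expression`` without testing the mutants against each
other.  Genes fitting none of the patterns are ``unclassified``.

Gene-gene coupling within single cells (the shared RA response) is measured
as the Spearman rank correlation of per-cell densities, one coefficient per
biological replicate, optionally resolved by AP-position quartile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import density

__all__ = [
    "ReplicateSummary",
    "ClassCall",
    "CorrelationResult",
    "replicate_means",
    "classify_gene",
    "classify_panel",
    "spearman_by_replicate",
    "quartile_partition",
    "QUARTILE_LABELS",
]


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-replicate summary of one gene in one genotype/age group."""

    gene: str
    genotype: str
    age: float
    replicate_id: str
    mean_density: float  # transcripts/um^3
    mean_transcripts: float  # raw transcripts per cell (low-expression guard)
    n_cells: int


@dataclass(frozen=True)
class ClassCall:
    gene: str
    class_label: str  # class1 | class2 | class3 | low_expression | unclassified
    p_wt_vs_stra8: float
    p_stra8_vs_dazl: float
    p_wt_vs_dazl: float
    direction_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    genotype: str
    replicate_id: str
    rho: float
    n_cells: int
    quartile: str | None = None


def replicate_means(cells: pd.DataFrame, gene: str) -> list[ReplicateSummary]:
    """One summary per (genotype, age, replicate): mean density over cells."""
    if "replicate_id" not in cells.columns:
        raise ValueError("cells must be annotated with replicate_id")
    out = []
    for (genotype, age, rep), grp in cells.groupby(
            ["genotype", "age", "replicate_id"], sort=True):
        if len(grp) == 0:
            raise ValueError(f"replicate {rep} has zero cells")
        out.append(ReplicateSummary(
            gene=gene,
            genotype=str(genotype),
            age=float(age),
            replicate_id=str(rep),
            mean_density=float(density(grp, gene).mean()),
            mean_transcripts=float(grp[gene].mean()),
            n_cells=len(grp),
        ))
    return out


def _welch(a: list[ReplicateSummary], b: list[ReplicateSummary]) -> tuple[float, float]:
    """Two-sided Welch t-test on replicate mean densities; returns (p, diff)."""
    xa = np.array([s.mean_density for s in a])
    xb = np.array([s.mean_density for s in b])
    res = stats.ttest_ind(xa, xb, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if np.isclose(xa.mean(), xb.mean()) else 0.0
    return p, float(xa.mean() - xb.mean())


def classify_gene(
    wt: list[ReplicateSummary],
    stra8_null: list[ReplicateSummary],
    dazl_null: list[ReplicateSummary],
    alpha: float = 0.05,
) -> ClassCall:
    """Assign a Stra8-dependency class from the three pairwise contrasts.

    The decision table is exhaustive: every combination of significance
    outcomes maps to exactly one label.
    """
    for name, grp in (("wildtype", wt), ("stra8_null", stra8_null),
                      ("dazl_null", dazl_null)):
        if len(grp) < 2:
            raise ValueError(f"need >=2 replicates in {name}")
    gene = wt[0].gene

    # grand mean transcripts per cell, cell-weighted across replicates
    def per_cell(group: list[ReplicateSummary]) -> float:
        n = sum(s.n_cells for s in group)
        return sum(s.mean_transcripts * s.n_cells for s in group) / n

    p_ws, d_ws = _welch(wt, stra8_null)
    p_wd, d_wd = _welch(wt, dazl_null)

    if per_cell(stra8_null) < 1.0 and per_cell(dazl_null) < 1.0:
        return ClassCall(gene, "low_expression", p_ws, np.nan, p_wd,
                         ("mutant_expression_below_1_per_cell",))

    p_sd, d_sd = _welch(stra8_null, dazl_null)
    wt_above_stra8 = p_ws < alpha and d_ws > 0
    wt_below_stra8 = p_ws < alpha and d_ws < 0
    stra8_above_dazl = p_sd < alpha and d_sd > 0

    flags = []
    if wt_below_stra8:
        flags.append("elevated_in_stra8_null")
    if stra8_above_dazl:
        if wt_above_stra8:
            label = "class2"
        else:
            label = "class1"
    else:
        label = "class3" if wt_above_stra8 else "unclassified"
    return ClassCall(gene, label, p_ws, p_sd, p_wd, tuple(flags))


def classify_panel(
    cells: pd.DataFrame,
    genes: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Class-call table for a cell table containing all three genotypes."""
    meta = {"cell_id", "replicate_id", "genotype", "tissue", "age",
            "ap_position", "volume", "ra_factor"}
    if genes is None:
        genes = [c for c in cells.columns if c not in meta]
    rows = []
    for gene in genes:
        summaries = replicate_means(cells, gene)
        by_gt = {}
        for s in summaries:
            by_gt.setdefault(s.genotype, []).append(s)
        call = classify_gene(by_gt.get("wildtype", []),
                             by_gt.get("stra8_null", []),
                             by_gt.get("dazl_null", []), alpha=alpha)
        rows.append({
            "gene": call.gene, "class": call.class_label,
            "p_wt_vs_stra8": call.p_wt_vs_stra8,
            "p_stra8_vs_dazl": call.p_stra8_vs_dazl,
            "p_wt_vs_dazl": call.p_wt_vs_dazl,
            "direction_flags": ";".join(call.direction_flags) or ".",
        })
    return pd.DataFrame(rows)


def spearman_by_replicate(
    cells: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    quartile: str | None = None,
) -> list[CorrelationResult]:
    """Spearman correlation of per-cell densities, one result per replicate.

    Ties are handled by midranks (scipy default).
    """
    out = []
    for rep, grp in cells.groupby("replicate_id", sort=True):
        if len(grp) < 3:
            raise ValueError(f"replicate {rep} has fewer than 3 cells")
        da = density(grp, gene_a)
        db = density(grp, gene_b)
        rho = stats.spearmanr(da, db).statistic
        out.append(CorrelationResult(
            gene_a=gene_a, gene_b=gene_b,
            genotype=str(grp["genotype"].iloc[0]),
            replicate_id=str(rep), rho=float(rho), n_cells=len(grp),
            quartile=quartile,
        ))
    return out


QUARTILE_LABELS = ("posteriormost", "mid_posterior", "mid_anterior", "anteriormost")


def quartile_partition(cells: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split one ovary's cells into AP-position quarters.

    Half-open bins [0, .25), [.25, .5), [.5, .75) and the closed top bin
    [.75, 1]; the union of the four bins is the input.
    """
    pos = cells["ap_position"]
    bins = {
        "posteriormost": cells[(pos >= 0.0) & (pos < 0.25)],
        "mid_posterior": cells[(pos >= 0.25) & (pos < 0.5)],
        "mid_anterior": cells[(pos >= 0.5) & (pos < 0.75)],
        "anteriormost": cells[(pos >= 0.75) & (pos <= 1.0)],
    }
    return bins
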