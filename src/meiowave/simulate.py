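"""Synthetic single-cell smFISH data for the fetal-ovary meiotic induction wave.

Germ cells in the fetal ovary enter meiotic prophase in an anterior-to-posterior
wave: retinoic acid (RA) induces *Stra8* and, in parallel, a Stra8-independent
pathway, and meiotic-prophase genes differ in how much of their induction each
pathway contributes.  This module generates per-cell transcript-count tables
(one row per germ cell: position along the anterior-posterior (AP) axis, cell
volume, latent RA response, and integer transcript counts per gene) whose
statistical structure mirrors what the downstream trace, classification and
correlation analyses assume:

* a traveling induction front, linear in AP position;
* logistic rise (and, for pulse genes, logistic fall) of mean transcript
  density (transcripts per um^3) after local wave arrival;
* three regulatory classes -- fully Stra8-independent (class 1), partially
  Stra8-independent (class 2), fully Stra8-dependent (class 3);
* Dazl-dependence of every meiotic gene (Dazl-null cells stay at baseline);
* Stra8-dependent down-regulation: in Stra8-null cells pulse genes never fall,
  and the Stra8-independent component may be mildly elevated;
* a shared lognormal per-cell RA-response factor that induces positive
  gene-gene correlations; and
* negative-binomial count noise on volume-scaled means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GeneModel",
    "SimulationParams",
    "META_COLUMNS",
    "default_panel",
    "default_params",
    "expected_class_call",
    "wave_arrival_time",
    "mean_density",
    "simulate_ovary",
    "simulate_replicates",
    "density",
]

GENOTYPES = ("wildtype", "stra8_null", "dazl_null", "kit_null", "stra8_het")
#: genotypes with at least one functional Stra8 allele
_STRA8_FUNCTIONAL = ("wildtype", "stra8_het", "dazl_null", "kit_null")

REG_CLASSES = ("class1", "class2", "class3", "pluripotency", "somatic", "reporter")

#: fixed metadata columns of a cell table; all remaining columns are gene counts
META_COLUMNS = [
    "cell_id",
    "replicate_id",
    "genotype",
    "tissue",
    "age",
    "ap_position",
    "volume",
    "ra_factor",
]


@dataclass(frozen=True)
class GeneModel:
    """Deterministic expression model for one gene.

    Mean transcript density (transcripts/um^3) is
    ``baseline + ra_factor * amplitude * [(1-f)*rise(s) + f*rise(s)] * fall(s)``
    where ``f`` is ``stra8_fraction``, ``s`` is time since local wave arrival
    minus ``induction_delay``, and ``fall`` applies only to pulse genes in
    cells with functional Stra8.
    """

    name: str
    reg_class: str
    amplitude: float = 0.03
    stra8_fraction: float = 0.5
    induction_delay: float = 0.0
    rise_rate: float = 4.0
    fall_rate: float = 6.0
    pulse: bool = False
    pulse_width: float = 0.8  # days between rise and fall midpoints
    baseline: float = 0.003
    stra8_null_gain: float = 1.0
    dazl_dependent: bool = True
    somatic_level: float = 0.5  # bulk somatic background, FPKM units
    somatic_level_testis: float | None = None  # testis somatic background, if different
    testis_fraction: float = 0.0  # fraction of ovary germ-cell level in testis

    def __post_init__(self) -> None:
        if self.reg_class not in REG_CLASSES:
            raise ValueError(f"unknown regulatory class {self.reg_class!r}")
        if not (0.0 <= self.stra8_fraction <= 1.0):
            raise ValueError("stra8_fraction must lie in [0, 1]")
        if self.reg_class == "class1" and self.stra8_fraction != 0.0:
            raise ValueError("class1 genes are fully Stra8-independent")
        if self.reg_class == "class3" and self.stra8_fraction != 1.0:
            raise ValueError("class3 genes are fully Stra8-dependent")
        if self.amplitude < self.baseline or self.baseline < 0:
            raise ValueError("require amplitude >= baseline >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic ovary/testis experiment."""

    gene_panel: tuple[GeneModel, ...]
    wave_anterior_onset: float = 13.0  # embryonic day the front reaches ap=1
    wave_span: float = 2.0  # days for the front to travel anterior->posterior
    dispersion_phi: float = 0.15  # NB overdispersion of per-cell counts
    bulk_dispersion_phi: float = 0.04  # replicate-level NB overdispersion of
    # bulk counts (squared biological CV; inbred-littermate scale)
    ra_sigma: float = 0.4  # log-scale SD of the shared RA-response factor
    volume_log_mean: float = float(np.log(500.0))  # um^3, lognormal median 500
    volume_log_sigma: float = 0.25
    cells_per_ovary: int = 300
    ages: tuple[float, ...] = (11.5, 12.5, 13.5, 14.0, 14.5, 15.0, 15.5, 16.5)
    genotypes: tuple[str, ...] = ("wildtype", "stra8_null", "dazl_null")
    ra_pulse_age: float | None = None  # embryonic day of exogenous RA, if any
    refractory: bool = True  # cells that completed the Stra8 pulse ignore later RA

    def __post_init__(self) -> None:
        if self.wave_span <= 0:
            raise ValueError("wave_span must be positive")
        if self.dispersion_phi < 0:
            raise ValueError("dispersion_phi must be non-negative")

    def gene(self, name: str) -> GeneModel:
        for g in self.gene_panel:
            if g.name == name:
                return g
        raise KeyError(f"gene {name!r} not in panel")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.gene_panel]


def default_panel() -> tuple[GeneModel, ...]:
    """The 13-gene smFISH panel plus Stra8, its promoter reporter, and
    pluripotency markers.

    Rec8 (class 1) carries a mild Stra8-null gain and a somatic component
    (it is not germ-cell-enriched in bulk tissue).  The cohesins/early class-2
    genes rise contemporaneously with Stra8; the synaptonemal-complex class-2
    genes slightly later; class-3 genes later still.  Mei1 and Msh5 sit at a
    baseline below one transcript per median cell, so in both mutants they
    fall under the low-expression reporting guard.
    """
    g = []
    # Stra8: RA-induced pulse, fall requires functional STRA8
    g.append(GeneModel("Stra8", "class1", amplitude=0.06, stra8_fraction=0.0,
                       pulse=True, pulse_width=0.6, stra8_null_gain=1.0))
    # lacZ knocked into the Stra8 locus: same promoter dynamics
    g.append(GeneModel("Stra8lacZ", "reporter", amplitude=0.06,
                       stra8_fraction=0.0, pulse=True, pulse_width=0.6))
    # class 1: fully Stra8-independent, pulse, elevated without Stra8
    g.append(GeneModel("Rec8", "class1", amplitude=0.04, stra8_fraction=0.0,
                       pulse=True, pulse_width=0.6, stra8_null_gain=1.3,
                       baseline=0.001, somatic_level=2.5,
                       somatic_level_testis=0.3))
    # class 2, early: induced slightly ahead of the wave front so their
    # half-max precedes or coincides with Stra8's (whose pulse peaks early)
    for name in ("Stag3", "Smc1b", "Gm1564"):
        g.append(GeneModel(name, "class2", amplitude=0.03, stra8_fraction=0.5,
                           induction_delay=-0.2))
    # class 2, slightly later synaptonemal-complex / uncharacterized genes
    for name in ("Sycp1", "Sycp2", "Sycp3", "Ugt8a"):
        g.append(GeneModel(name, "class2", amplitude=0.03, stra8_fraction=0.5,
                           induction_delay=0.3))
    # class 3: fully Stra8-dependent, late
    for name in ("Dmc1", "Hormad1", "M1ap"):
        g.append(GeneModel(name, "class3", amplitude=0.03, stra8_fraction=1.0,
                           induction_delay=0.75))
    for name in ("Mei1", "Msh5"):
        g.append(GeneModel(name, "class3", amplitude=0.03, stra8_fraction=1.0,
                           induction_delay=0.75, baseline=0.0008))
    # pluripotency markers: high early, down-regulated as meiosis begins
    for name in ("Pou5f1", "Nanog", "Sox2"):
        g.append(GeneModel(name, "pluripotency", amplitude=0.03,
                           stra8_fraction=0.0, dazl_dependent=False,
                           testis_fraction=1.0))
    return tuple(g)


#: the 13 genes examined by smFISH, in panel order
SMFISH_PANEL = ("Rec8", "Stag3", "Smc1b", "Gm1564", "Sycp1", "Sycp2", "Sycp3",
                "Ugt8a", "Dmc1", "Hormad1", "M1ap", "Mei1", "Msh5")


def default_params(**overrides) -> SimulationParams:
    return SimulationParams(gene_panel=default_panel(), **overrides)


def expected_class_call(gene: GeneModel, params: SimulationParams) -> str:
    """Class call the generative model implies for ``gene``.

    Matches the classification decision table: genes whose mutant-genotype
    expression averages below one transcript per (median-volume) cell are
    reported as ``low_expression`` rather than by regulatory class.
    """
    if gene.reg_class not in ("class1", "class2", "class3"):
        raise ValueError("expected call defined for class 1/2/3 genes only")
    median_volume = float(np.exp(params.volume_log_mean))
    mutant_means = []
    for genotype in ("stra8_null", "dazl_null"):
        dens = [
            mean_density(gene, genotype, age, u, 1.0, params)
            for age in params.ages
            for u in np.linspace(0, 1, 21)
        ]
        mutant_means.append(float(np.mean(dens)) * median_volume)
    if all(m < 1.0 for m in mutant_means):
        return "low_expression"
    return gene.reg_class


def wave_arrival_time(ap_position, params: SimulationParams):
    """Embryonic day the induction front reaches an AP position.

    The front moves at constant speed from the anterior pole (``ap=1``,
    reached at ``wave_anterior_onset``) to the posterior pole (``ap=0``,
    reached ``wave_span`` days later).
    """
    ap = np.asarray(ap_position, dtype=float)
    if np.any(ap < 0) or np.any(ap > 1):
        raise ValueError("ap_position must lie in [0, 1]")
    out = params.wave_anterior_onset + (1.0 - ap) * params.wave_span
    return float(out) if np.isscalar(ap_position) else out


def _rise(s, rate):
    return expit(rate * np.asarray(s, dtype=float))


def _fall(s, gene: GeneModel):
    """Logistic down-regulation factor, midpoint ``pulse_width`` after rise."""
    return 1.0 - expit(gene.fall_rate * (np.asarray(s, dtype=float) - gene.pulse_width))


def _pulse_completed(s, gene: GeneModel):
    """A cell has completed the pulse once the fall is past its midpoint."""
    return np.asarray(s, dtype=float) > gene.pulse_width


def mean_density(
    gene: GeneModel,
    genotype: str,
    age: float,
    ap_position,
    ra_factor,
    params: SimulationParams,
    tissue: str = "ovary",
):
    """Deterministic mean transcript density (transcripts/um^3) of one gene.

    Vectorized over ``ap_position`` / ``ra_factor``.  ``tissue='testis'``
    cells are never reached by the ovarian wave but remain competent to
    respond to an exogenous RA pulse (``params.ra_pulse_age``).
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if age < 0:
        raise ValueError("age must be non-negative")
    ap = np.asarray(ap_position, dtype=float)
    ra = np.asarray(ra_factor, dtype=float)
    scalar = np.isscalar(ap_position) and np.isscalar(ra_factor)
    ap, ra = np.broadcast_arrays(ap, ra)

    out = np.full(ap.shape, gene.baseline, dtype=float)

    dazl_functional = genotype != "dazl_null"
    stra8_functional = genotype in _STRA8_FUNCTIONAL
    germline = genotype != "kit_null"

    if gene.reg_class == "somatic":
        out = np.full(ap.shape, gene.baseline + gene.amplitude, dtype=float)
        return float(out[()]) if scalar else out

    if not germline:
        return float(out[()]) if scalar else out

    if gene.reg_class == "pluripotency":
        # high early; declines when the wave arrives, requires Dazl (competence)
        if tissue == "ovary" and dazl_functional:
            s = age - gene.induction_delay - wave_arrival_time(ap, params)
            out = gene.baseline + gene.amplitude * (1.0 - _rise(s, gene.rise_rate))
        else:
            out = np.full(ap.shape, gene.baseline + gene.amplitude, dtype=float)
        return float(out[()]) if scalar else out

    # meiotic-program genes (class1/2/3, reporter)
    if gene.dazl_dependent and not dazl_functional:
        return float(out[()]) if scalar else out

    induced = np.zeros(ap.shape, dtype=float)
    if tissue == "ovary":
        s = age - gene.induction_delay - wave_arrival_time(ap, params)
        independent = _rise(s, gene.rise_rate)
        dependent = _rise(s, gene.rise_rate) if stra8_functional else 0.0
        gain = 1.0 if stra8_functional else gene.stra8_null_gain
        induced = (1.0 - gene.stra8_fraction) * gain * independent \
            + gene.stra8_fraction * dependent
        if gene.pulse and stra8_functional:
            induced = induced * _fall(s, gene)

    # exogenous RA pulse drives the Stra8-independent component; ovary cells
    # that completed the endogenous Stra8 pulse are refractory
    if params.ra_pulse_age is not None and age >= params.ra_pulse_age:
        stra8_gene = params.gene("Stra8") if gene.name != "Stra8" else gene
        response = (1.0 - gene.stra8_fraction) * _rise(
            age - params.ra_pulse_age, gene.rise_rate)
        if tissue == "ovary" and params.refractory:
            s_stra8 = age - stra8_gene.induction_delay - wave_arrival_time(ap, params)
            responsive = ~_pulse_completed(s_stra8, stra8_gene)
            response = response * responsive
        induced = np.maximum(induced, response)

    out = gene.baseline + ra * gene.amplitude * induced
    return float(out[()]) if scalar else out


def _nb_counts(rng: np.random.Generator, mean, phi: float) -> np.ndarray:
    """Negative-binomial counts with variance ``m + phi m^2`` (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    # gamma-Poisson mixture keeps the parametrization explicit
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_ovary(
    genotype: str,
    age: float,
    params: SimulationParams,
    seed,
    replicate_id: str | None = None,
    tissue: str = "ovary",
    n_cells: int | None = None,
) -> pd.DataFrame:
    """Simulate one gonad: a cell table with per-gene transcript counts.

    AP positions are uniform on [0, 1]; volumes lognormal; a lognormal
    RA-response factor is shared by all genes within a cell; counts are
    negative binomial around ``mean_density * volume``.  Identical seeds give
    identical tables.
    """
    n = params.cells_per_ovary if n_cells is None else int(n_cells)
    if n < 1:
        raise ValueError("need at least one cell per ovary")
    rng = np.random.default_rng(seed)
    rep = replicate_id if replicate_id is not None else f"{genotype}_{age}_r0"

    ap = rng.uniform(0.0, 1.0, size=n)
    volume = rng.lognormal(params.volume_log_mean, params.volume_log_sigma, size=n)
    ra = rng.lognormal(-0.5 * params.ra_sigma**2, params.ra_sigma, size=n)

    table = pd.DataFrame(
        {
            "cell_id": [f"{rep}_c{i:04d}" for i in range(n)],
            "replicate_id": rep,
            "genotype": genotype,
            "tissue": tissue,
            "age": float(age),
            "ap_position": ap,
            "volume": volume,
            "ra_factor": ra,
        }
    )
    for gene in params.gene_panel:
        mu = mean_density(gene, genotype, age, ap, ra, params, tissue=tissue) * volume
        table[gene.name] = _nb_counts(rng, mu, params.dispersion_phi)
    table.attrs["provenance"] = {
        "seed": seed, "genotype": genotype, "age": float(age), "tissue": tissue,
    }
    return table


def simulate_replicates(
    genotype: str,
    age: float,
    params: SimulationParams,
    master_seed: int,
    n_replicates: int = 3,
    tissue: str = "ovary",
    n_cells: int | None = None,
) -> pd.DataFrame:
    """Independent biological replicates (one simulated gonad each).

    Per-replicate seeds are spawned deterministically from the master seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    children = np.random.SeedSequence(master_seed).spawn(n_replicates)
    tables = [
        simulate_ovary(genotype, age, params, seed=children[i],
                       replicate_id=f"{genotype}_{age}_r{i}", tissue=tissue,
                       n_cells=n_cells)
        for i in range(n_replicates)
    ]
    out = pd.concat(tables, ignore_index=True)
    out.attrs["provenance"] = {"master_seed": master_seed, "genotype": genotype,
                               "age": float(age), "tissue": tissue,
                               "n_replicates": n_replicates}
    return out


def density(cells: pd.DataFrame, gene: str) -> pd.Series:
    """Per-cell transcript density: count / volume (transcripts/um^3)."""
    return cells[gene] / cells["volume"]
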