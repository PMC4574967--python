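"""Synthetic whole-gonad RNA-seq count matrices.

Bulk samples are modeled as two-compartment mixtures of germ and somatic
cells.  A gene's tissue-level abundance is

``T = germ_fraction * G + (1 - germ_fraction) * S``

where ``G`` is the germ-cell expression implied by the single-cell wave model
(averaged over the sampled AP segment) and ``S`` is a somatic background.
Expected read counts are proportional to library size, gene length and ``T``,
normalized per sample by total transcript mass (so per-million units are
compositional, as in real RNA-seq); counts carry negative-binomial noise.
Germ-cell-depleted (Kit-mutant) gonads have ``germ_fraction = 0`` and hence
near-baseline meiotic-gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rnaseq import CountMatrix
from .simulate import GeneModel, SimulationParams, default_panel, mean_density

__all__ = [
    "BulkSample",
    "BulkDesign",
    "DEFAULT_GERM_FRACTION",
    "default_bulk_panel",
    "default_bulk_design",
    "anterior_posterior_design",
    "expected_fpkm",
    "simulate_bulk_counts",
]

DEFAULT_GERM_FRACTION = {
    "wildtype": 0.3,
    "stra8_null": 0.3,
    "dazl_null": 0.25,
    "stra8_het": 0.3,
    "kit_null": 0.0,  # germ-cell-depleted
}

#: converts germ-cell transcript density (transcripts/um^3) to FPKM-like units
GERM_FPKM_SCALE = 3000.0


@dataclass(frozen=True)
class BulkSample:
    sample_id: str
    tissue: str
    genotype: str
    age: float
    replicate: str
    library_size: float
    segment: tuple[float, float] = (0.0, 1.0)  # AP interval sampled

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


@dataclass
class BulkDesign:
    samples: list[BulkSample]
    gene_lengths: pd.Series  # bp
    germ_cell_fraction: dict = field(default_factory=lambda: dict(DEFAULT_GERM_FRACTION))

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("empty design")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": [s.tissue for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "age": [s.age for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "library_size": [s.library_size for s in self.samples],
                "segment_lo": [s.segment[0] for s in self.samples],
                "segment_hi": [s.segment[1] for s in self.samples],
            },
            index=pd.Index([s.sample_id for s in self.samples], name="sample_id"),
        )


def _germ_expression(
    gene: GeneModel,
    genotype: str,
    age: float,
    segment: tuple[float, float],
    params: SimulationParams,
    tissue: str,
) -> float:
    """Mean germ-cell expression over an AP segment, FPKM-like units."""
    if tissue == "testis" and gene.reg_class in ("class1", "class2", "class3",
                                                 "reporter"):
        # testicular germ cells are not swept by the wave; shared germline
        # genes are expressed at a constant fraction of the ovarian amplitude
        dens = gene.baseline + gene.testis_fraction * gene.amplitude
        return GERM_FPKM_SCALE * dens
    u = np.linspace(segment[0], segment[1], 25)
    dens = mean_density(gene, genotype, age, u, 1.0, params, tissue=tissue)
    return GERM_FPKM_SCALE * float(np.mean(dens))


def expected_fpkm(
    design: BulkDesign,
    params: SimulationParams,
) -> pd.DataFrame:
    """Deterministic expected FPKM table (genes x samples) for a design."""
    panel = {g.name: g for g in params.gene_panel}
    missing = set(panel) - set(design.gene_lengths.index)
    if missing:
        raise ValueError(f"gene lengths missing for {sorted(missing)}")
    genes = list(panel)
    len_kb = design.gene_lengths.loc[genes].to_numpy(dtype=float) / 1e3

    raw = np.zeros((len(genes), len(design.samples)))
    for j, s in enumerate(design.samples):
        frac = design.germ_cell_fraction.get(s.genotype)
        if frac is None:
            raise KeyError(f"no germ_cell_fraction for genotype {s.genotype!r}")
        for i, name in enumerate(genes):
            g = panel[name]
            if g.reg_class == "somatic":
                raw[i, j] = g.somatic_level
                continue
            G = _germ_expression(g, s.genotype, s.age, s.segment, params, s.tissue)
            som = g.somatic_level
            if s.tissue == "testis" and g.somatic_level_testis is not None:
                som = g.somatic_level_testis
            raw[i, j] = frac * G + (1.0 - frac) * som
    # compositional normalization: per-million units scale with the total
    # transcript mass of each sample
    mass = (raw * len_kb[:, None]).sum(axis=0)
    ref = np.exp(np.mean(np.log(mass)))
    fpkm = raw * (ref / mass)[None, :]
    return pd.DataFrame(fpkm, index=pd.Index(genes, name="gene"),
                        columns=[s.sample_id for s in design.samples])


def simulate_bulk_counts(
    design: BulkDesign,
    params: SimulationParams,
    seed,
    phi: float | None = None,
) -> CountMatrix:
    """Sample a negative-binomial count matrix around the expected FPKM.

    ``expected count = FPKM * gene_length_kb * library_size / 1e6``, so counts
    are proportional to library size, gene length and tissue-level expression.
    """
    if phi is None:
        phi = params.bulk_dispersion_phi
    fpkm = expected_fpkm(design, params)
    len_kb = design.gene_lengths.loc[fpkm.index].to_numpy(dtype=float) / 1e3
    libs = np.array([s.library_size for s in design.samples], dtype=float)
    lam = fpkm.to_numpy() * len_kb[:, None] * libs[None, :] / 1e6

    rng = np.random.default_rng(seed)
    if phi == 0:
        counts = rng.poisson(lam)
    else:
        r = 1.0 / phi
        counts = rng.poisson(rng.gamma(shape=r, scale=lam / r))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=fpkm.index, columns=fpkm.columns),
        sample_meta=design.meta_frame(),
        gene_lengths=design.gene_lengths.loc[fpkm.index],
        library_sizes=pd.Series(libs, index=fpkm.columns),
    )
    return cm


def default_bulk_panel(
    n_meiotic_extra: int = 40,
    n_shared: int = 15,
    n_somatic: int = 120,
    n_silent: int = 30,
    seed: int = 20150917,
) -> tuple[GeneModel, ...]:
    """Gene panel for bulk simulations: the smFISH panel plus planted fillers.

    Adds randomly parameterized meiotic-program genes (the planted positives),
    germline-shared genes expressed in both fetal ovary and testis, somatic
    genes, and silent genes below the expression filter.  The somatic
    background is deliberately the majority of the universe so that
    trimmed-mean library normalization (which assumes most genes are not
    differential) is well posed.  The seed fixes the filler parameters; it is
    a panel identity, not a noise seed.
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in default_panel() if g.name != "Stra8lacZ"]
    for i in range(n_meiotic_extra):
        cls = ("class1", "class2", "class3")[int(rng.integers(3))]
        frac = {"class1": 0.0, "class2": float(rng.uniform(0.3, 0.7)),
                "class3": 1.0}[cls]
        genes.append(GeneModel(
            name=f"Meio{i:03d}", reg_class=cls,
            amplitude=float(rng.uniform(0.025, 0.05)), stra8_fraction=frac,
            induction_delay=float(rng.uniform(0.0, 1.0)),
            pulse=bool(rng.random() < 0.5),
        ))
    for i in range(n_shared):
        genes.append(GeneModel(
            name=f"Shared{i:03d}", reg_class="class2",
            amplitude=float(rng.uniform(0.02, 0.05)), stra8_fraction=0.5,
            induction_delay=float(rng.uniform(0.0, 0.5)),
            testis_fraction=1.0,
        ))
    for i in range(n_somatic):
        genes.append(GeneModel(
            name=f"Soma{i:03d}", reg_class="somatic", amplitude=0.0,
            stra8_fraction=0.0, baseline=0.0,
            somatic_level=float(rng.uniform(10.0, 60.0))))
    for i in range(n_silent):
        genes.append(GeneModel(
            name=f"Silent{i:03d}", reg_class="somatic", amplitude=0.0,
            stra8_fraction=0.0, baseline=0.0,
            somatic_level=float(rng.uniform(0.05, 0.5))))
    return tuple(genes)


def _lengths_for(names: list[str], seed: int = 7) -> pd.Series:
    rng = np.random.default_rng(seed)
    lengths = np.round(rng.lognormal(np.log(2000.0), 0.4, size=len(names)))
    return pd.Series(lengths, index=pd.Index(names, name="gene"), name="length_bp")


def default_bulk_design(
    panel: tuple[GeneModel, ...],
    n_replicates: int = 3,
    library_size: float = 1e7,
    ages: tuple[float, ...] = (12.5, 14.5, 16.5),
) -> BulkDesign:
    """Wild-type ovary, germ-cell-depleted ovary, and wild-type testis at
    three embryonic days: the design behind the filter cascade."""
    samples = []
    for tissue, genotype in (("ovary", "wildtype"), ("ovary", "kit_null"),
                             ("testis", "wildtype")):
        for age in ages:
            for r in range(n_replicates):
                gt_tag = "kit" if genotype == "kit_null" else "wt"
                samples.append(BulkSample(
                    sample_id=f"{tissue}_{gt_tag}_E{age}_r{r}",
                    tissue=tissue, genotype=genotype, age=age,
                    replicate=f"r{r}", library_size=library_size,
                ))
    return BulkDesign(samples=samples,
                      gene_lengths=_lengths_for([g.name for g in panel]))


def anterior_posterior_design(
    panel: tuple[GeneModel, ...],
    n_replicates: int = 3,
    library_size: float = 1e7,
) -> BulkDesign:
    """Ovary thirds at two ages, for the change-over-time vs change-over-space
    comparison: E12.5 anterior, E13.5 anterior, E13.5 posterior."""
    thirds = {"ant": (2.0 / 3.0, 1.0), "post": (0.0, 1.0 / 3.0)}
    spec_rows = [(12.5, "ant"), (13.5, "ant"), (13.5, "post")]
    samples = []
    for age, part in spec_rows:
        for r in range(n_replicates):
            samples.append(BulkSample(
                sample_id=f"ovary_{part}_E{age}_r{r}",
                tissue="ovary", genotype="wildtype", age=age,
                replicate=f"r{r}", library_size=library_size,
                segment=thirds[part],
            ))
    return BulkDesign(samples=samples,
                      gene_lengths=_lengths_for([g.name for g in panel]))
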