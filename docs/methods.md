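# Methods

This note records the models behind `meiowave`, the defaults and why they
were chosen, the numerical conventions, and the limits of what the synthetic
data can show.

## The traveling-wave expression model

Meiotic induction is modeled as a front moving at constant speed along the
anterior-posterior (AP) axis. With AP position `u ∈ [0, 1]` (0 = posterior
pole, 1 = anterior pole), the front reaches `u` at

```
t_arr(u) = wave_anterior_onset + (1 − u) · wave_span .
```

A gene's mean transcript density (transcripts·µm⁻³) in a cell at age `t` is

```
µ(u, t) = baseline + ra · A · [(1 − f) · gain · rise(s) + f · dep(s)] · fall(s)
s = t − induction_delay − t_arr(u)
```

where `A` is the amplitude, `f = stra8_fraction` apportions the induction
between the Stra8-independent and Stra8-dependent pathways, `rise(s) =
logistic(rise_rate · s)`, `dep(s)` equals `rise(s)` in Stra8-functional
cells and 0 otherwise, `gain = stra8_null_gain` only in Stra8-null cells,
and `fall(s) = 1 − logistic(fall_rate · (s − pulse_width))` applies only to
pulse genes **and only when functional STRA8 is present** — down-regulation
of *Stra8* and *Rec8* is itself Stra8-dependent, which is what makes these
transcripts persist (and *Rec8* run mildly high) in Stra8-null germ cells.
`ra` is a per-cell lognormal RA-response factor (mean exactly 1) shared by
all genes in a cell; it is what couples RA-driven genes in single-cell
correlations. Dazl-dependent genes sit at `baseline` in Dazl-null cells;
pluripotency genes run the mirror-image program (high early, declining at
wave arrival, no decline without *Dazl*); Kit-mutant tissue has no germ
cells.

The linear front and the logistic product shapes are the simplest smooth
forms consistent with a directional wave and with pulse vs. sustained
vs. late expression classes; the refractory state is binary per cell,
triggered once the *Stra8* fall passes its midpoint, after which exogenous
RA (an optional pulse at `ra_pulse_age`) no longer induces the
Stra8-independent component in ovarian cells. Testicular germ cells, never
reached by the wave, remain responsive — a simulated E15.5 RA pulse gives a
~20-fold *Stra8* induction in testis at E16.5 and none in ovary.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| ages | E11.5, 12.5, 13.5, 14.0, 14.5, 15.0, 15.5, 16.5 | the smFISH sampling grid |
| `wave_anterior_onset` | E13.0 | anterior induction begins shortly before E13.5 |
| `wave_span` | 2.0 d | posterior pole induced by ~E15; one age step = 0.25-0.5 axis units |
| `rise_rate` / `fall_rate` | 4 / 6 d⁻¹ | rise over ~1 d, sharper fall |
| `pulse_width` | 0.8 d (0.6 d for *Stra8*, reporter, *Rec8*) | a single restricted pulse; the shorter panel pulse reproduces near-complete *Rec8* down-regulation in the anteriormost quarter at E14.5 while E12.5 remains pre-induction |
| amplitudes | 0.03 µm⁻³ (0.06 *Stra8*, 0.04 *Rec8*) | tens of transcripts per ~500 µm³ cell at peak |
| `baseline` | 0.003 µm⁻³ (~1.5 transcripts/cell); *Mei1*/*Msh5* 0.0008 | keeps mutant floors testable; *Mei1*/*Msh5* deliberately sit under the 1-transcript/cell reporting guard, as their mutants do |
| `induction_delay` | −0.2 d early cohesin group; +0.3 d synaptonemal group; +0.75 d class 3 | orders half-max times: early class-1/2 at or before *Stra8*, class 3 after |
| `dispersion_phi` (cells) | 0.15 | overdispersion of per-cell smFISH counts beyond Poisson |
| `bulk_dispersion_phi` | 0.04 | replicate-level biological CV ≈ 20%, inbred-littermate scale — a different quantity from per-cell noise |
| `ra_sigma` | 0.4 | per-cell RA response CV ~40%, enough to produce ρ ≈ 0.3–0.7 gene-gene correlations |
| volumes | lognormal, median 500 µm³, σ = 0.25 | ~10 µm germ cells |
| `cells_per_ovary` / replicates | 300 / 3 | hundreds of scored germ cells per sectioned ovary; ≥2 biological replicates required for classification |

The wave timing, pulse widths and *Rec8* bulk levels were calibrated jointly
so that one parameter set reproduces all the qualitative anchors at once:
pre-induction at E12.5 (so meiotic genes pass the temporal up-regulation
filter), anteriormost-quarter *Rec8* down-regulation at E14.5, the induction
ordering, and *Rec8*'s bulk profile (germ-cell-expressed but not
germ-cell-enriched, hence the manual include list).

### Bulk counts

A bulk sample is a two-compartment mixture: gene abundance `T =
germ_fraction · G + (1 − germ_fraction) · S`, with `G` the wave model's
germ-cell expression averaged over the sampled AP segment (scaled to
FPKM-like units, 3000 FPKM per transcript·µm⁻³ at 30% germ cells) and `S` a
somatic background (testis-specific for *Rec8*). Expected counts are
`library_size · gene_length · T`, normalized per sample by total transcript
mass, so per-million units are compositional as in real RNA-seq — this is
what lets germ-cell-depleted tissue inflate somatic genes. The default bulk
panel surrounds the 54 planted meiotic-program genes with a majority
somatic background (120 genes) so that trimmed-mean normalization, which
assumes most genes are not differential, is well posed; libraries default
to 10⁷ reads.

## Spatiotemporal traces

Windows: 100 evenly spaced centers, each window a fixed 0.2 of the ovary
length, slid inward at the poles so every window keeps its full width (a
window is a fraction of the organ, so the degenerate width-1 window is the
whole axis). Registration scans displacements on a 0.01 grid, minimizing
the mean squared difference between the earlier trace (linearly
interpolated) and the later trace over their overlap, with at least 25%
overlap required; ties break toward the smaller shift, and only full-width
interior windows enter the objective (edge windows are not translation
equivariant). A pair whose traces have a 10th-90th-percentile spread below
20% of the pair's peak is flagged ambiguous and abutted end-to-end —
quantile spread rather than range because a silent age's trace still
carries baseline noise. In practice this retires E11.5 (no *Stra8* yet) and
E16.5 (*Stra8* fallen) from the wild-type reference without manual
intervention. Shifts accumulate with age and are non-decreasing; joined
traces average overlapping windows weighted by cell counts within 0.01
coordinate bins. Half-max timing interpolates the first upward crossing of
50% of the trace's own maximum; traces whose maximum does not exceed a
tolerance are flagged undefined rather than assigned a time.

Mutant genotypes are placed on the wild-type-derived axis: a Stra8-null
*Stra8* trace saturates (no fall) and a Dazl-null one is flat, so neither
can self-register, and applying the wild-type shifts to all genotypes is
the only construction that keeps coordinates comparable across genotypes.

## Classification

Contrasts are two-sided Welch t-tests on replicate mean densities, with
direction taken from the sign of the difference; Welch because replicate
counts are 2-3 and variances need not match. The decision table is total:
low-expression guard first (both mutants' cell-weighted grand means under 1
raw transcript per cell — transcripts, not density, and the
mutant-vs-mutant contrast is then not run), then class 2 (wild type
significantly above Stra8-null, Stra8-null significantly above Dazl-null),
class 1 (not significantly reduced in Stra8-null but above Dazl-null; a
significant *increase* adds the `elevated_in_stra8_null` flag), class 3
(reduced in Stra8-null, indistinguishable from Dazl-null), else
unclassified. No multiple-testing correction is applied across genes —
class calls mirror per-gene p < 0.05 — a known limitation. Spearman
correlations use midranks and are computed per biological replicate, never
on pooled replicates; quartile bins are `[0, .25) [.25, .5) [.5, .75)
[.75, 1]`.

## Differential expression

Library normalization is a trimmed-mean-of-log-ratios factor (30% trim per
tail) against the geometric-mean reference profile over genes detected in
all samples, requiring at least 10 such genes. The exact test scales each
sample's count to the geometric-mean effective library size, rounds the
group totals, and enumerates the conditional distribution of the group-A
total given the grand total, with group sums distributed NB(n·µ, φ/n)
(Poisson at φ = 0); the two-sided p-value sums all outcomes no more
probable than the observed one (relative tie tolerance 1e-10). Fold changes
add a prior count of 0.25 per group mean. Dispersion: per-gene method of
moments on common-scale counts, with the denominator corrected to `m̂² −
v/n` (the naive `m̂²` is inflated by the sampling variance of the mean,
biasing φ low and the test anticonservative); the common dispersion is a
ratio-of-sums estimator across genes, and tagwise values shrink toward it
with 10 pseudo-samples. On null NB data (φ = 0.1, 3 vs 3, 2,000 genes) the
pipeline rejects ~5-6% at α = 0.05 and holds the empirical FDR under 0.03
at q < 0.01 with 10% planted 4-fold effects; this is re-measured, not
assumed, by the test suite and acceptance script. The cascade applies its
four stages in order with the any-age disjunction at stages 1, 2 and 4;
stage 3 (ovary vs testis) is a single contrast at the central assayed age
(E14.5) — pooling ages into one group inflates within-group dispersion and
guts power. Include-list genes are injected after stage 2, flagged as
manual, and must still pass stages 3-4. A gene-type table, when provided,
restricts the universe to coding genes; otherwise this is a no-op.

## k-means under correlation distance

Rows (log, mean-centered profiles) are compared by `1 − Pearson r`;
centroids are means of member profiles, re-centered. Rows with no dynamic
range have undefined correlation: they are flagged and assigned by a
fallback Euclidean rule in centered-profile space, which sends an exactly
flat row to the smallest-norm (degenerate) centroid — so flat rows pool
together rather than scatter. Seeding is D²-weighted (k-means++-style) over
all rows under the same mixed metric; empty clusters reseed from the point
farthest from its centroid; the best of 20 restarts by total within-cluster
distance wins. The planted-profile benchmark generates pulse / sustained /
late / declining shapes with Gaussian noise plus an exactly flat class: a
flat profile carries no shape information under correlation distance, so
noisy flat rows would be unassignable in principle; the zero-variance flat
class is what exercises the degenerate pathway.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses rely on —
wave geometry, pulse/sustained/late shapes, the three dependency classes,
Dazl gating, Stra8-dependent down-regulation and refractoriness, shared RA
response, NB counts, compositional bulk mixtures. It does not emulate:
segmentation or spot-detection error (densities are exact counts over exact
volumes), cell migration or proliferation (positions are static draws),
litter effects beyond independent replicate seeds, ambient RNA or mapping
artifacts in bulk counts, or a realistic genome-scale expression
distribution (the bulk universe is ~230 genes). Passing tests therefore
demonstrate that the analysis code recovers planted structure under the
assumed noise model, not that the biological findings would replicate from
raw images or reads; headline counts from the original deposited data
(e.g. gene-set sizes from GEO accession GSE70361) are not reproducible at
this scale and are out of scope.

## Validation problem sizes

The seeded validation suite runs single-cell simulations at 300 cells per
ovary and 3 replicates, 50 runs for class recovery, 20 seeds for
registration and quartile analyses, 2,000-gene count matrices for error
calibration, and a ~230-gene bulk design for the end-to-end cascade; these
sizes keep every check well inside a few minutes on one CPU while leaving
Monte-Carlo margins far from the pass thresholds.
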