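# Methods

This note documents the models, parameter choices and numerical
conventions behind `amygmap`, in the spirit of a package methods appendix:
what each stage assumes, which knobs matter, and what the bundled
synthetic data does and does not emulate.

## Single-cell stage

**Normalisation.** Counts are normalised to counts-per-million (CPM, not
per-10k) and the log layer is ln(1 + CPM). All printed thresholds are
interpreted on these scales with strict inequalities exactly as stated:
cells with total counts < 10,000 are excluded; Snap25 CPM < 250 marks a
cell non-neuronal; Gad1 CPM > 100 marks it an interneuron. Boundary values
(exactly 10,000 / 250 / 100) are retained in the neuronal/excitatory
classes.

**Variable genes.** Per gene, the mean statistic is ln(mean CPM + 1) and
the dispersion is ln(variance/mean of CPM); dispersions are z-scored
within 20 equal-width bins of the mean statistic, and genes with mean in
[0.125, 3] and z ≥ 1 are kept (the interneuron sub-analysis uses
0.0125 / 3 / 3, exposed as parameters). Zero-variance genes have undefined
dispersion and are excluded with a log entry.

**Clustering.** Cells are embedded by PCA on per-gene z-scored
log-expression; each component's sign is fixed by making its
largest-magnitude loading positive. The graph is k = 20 nearest
neighbours in the first 10 PCs, re-weighted by shared-nearest-neighbour
Jaccard similarity (neighbour sets include the cell itself) with edges
below 1/15 pruned, then clustered by Louvain modularity maximisation at
resolution 0.2 (coarse) or 0.8 (fine). Cluster labels are re-indexed in
decreasing size order so label 0 is always the largest cluster. The
Louvain pass consumes a seeded RNG, so results are reproducible.

**Differential expression.** A two-sided Wilcoxon rank-sum test per gene
on log-expression. The genome-wide screen is a vectorised tie-corrected
normal approximation with continuity correction; the scalar
`rank_sum_test` switches to the exact permutation distribution for small
tie-free samples. Bonferroni multiplies by the number of genes actually
tested: genes detected (CPM > 0) in fewer than 3 cells of the two groups
are not tested, and the denominator is logged. A cluster smaller than 3
cells is rejected — the test has no useful power there.

**Classifier stability.** Random forests (500 trees, default split
criteria) are trained on random cell subsets (50–800 cells, 100 replicates
per size by default) using variable-gene log-expression as features, and
predict all remaining cells. Training draws that miss a class are redrawn
and counted.

## Spatial registration

Landmark correspondence is by order (point i ↔ point i); no search. The
fit is the closed-form least-squares rigid transform (Kabsch): rotation
constrained to determinant +1, so a mirrored landmark set yields the best
proper rotation together with a large residual RMS, which is logged above
100 µm. Registered coordinates are re-expressed relative to the template's
dorsal-most point (y increases ventrally). The occasional manual
post-registration translation is deliberately *not* automated: the API
accepts a user-supplied shift and records it in the output's provenance.
Region assignment is half-open: a point on any LA edge — including the
shared LA/BA border — is assigned to LA; the rule is deterministic and
total over the plane.

The section templates (anterior / intermediate / posterior) are
hand-digitised polygons in µm, one shared shape at three scales, with a
slanted LA/BA border placing ~26% of the outline's area in the LA and two
optional BA subregions. They are a versioned fixture of this package with
no claim of atlas fidelity.

## Image stage

Segmentation follows three recipes: chromogenic signal is Gaussian-blurred,
thresholded and watershed-split, keeping components of 100–400 µm²; DAPI
nuclei are thresholded and watershed-split, filtered to 40–200 µm²
(interpreted as µm² although sometimes written as µm) *before* a 5 µm
isotropic dilation that grows surviving ROIs without letting neighbours
overlap (label expansion), with areas re-reported after dilation; Slc17a7
somata are blurred and thresholded with **no** watershed (the punctate
signal over-fragments), keeping 75–450 µm². All area filters are inclusive
at both bounds, because the stated rules discard strictly-less/greater
areas. Thresholds are per-channel configuration values; when omitted, an
inter-class-variance (Otsu) threshold is applied and logged as automatic.

Round-to-round alignment takes the integer-pixel phase-correlation peak of
the DAPI z-max projections for X/Y and of a z-x slice through the
strongest DAPI row for Z; subpixel refinement is deliberately off, since
the translations modelled are integer pixel shifts. CPA is the fraction of
an ROI's pixels whose (optionally pre-smoothed, for the noisy far-red
channels) probe intensity exceeds the channel threshold — a dimensionless
value in [0, 1], invariant to any rigid shift applied to ROI and probe
image together.

## Spatial statistics

The phenotype index (E_Cplx1 − E_Negr1)/(E_Cplx1 + E_Negr1) is undefined
when both markers are zero; such cells are excluded from phenotype
analyses. Winner-take-all phenotyping first gates on Slc17a7 ≥ 0.004 CPA,
then labels each cell by its higher-expressed marker; exact nonzero ties —
measure-zero in real data — break deterministically toward CPLX1 and are
counted in the log.

Correlation profiles use Pearson r between a seed cell's 12-gene CPA
vector and every other phenotyped cell in the same section (the full
panel, discrete markers included; a flag excludes them for sensitivity
analysis). Distances are Euclidean in the template frame; bins are
half-open, left-closed, 100 µm wide; the seed is excluded from its own
profile; cross-section pairs are never formed. Aggregation computes, per
bin and phenotype class, the mean and SD of per-seed bin means — i.e.
per-seed binning happens before pooling; a bin empty for a seed simply
contributes nothing, and a single-seed bin reports SD 0 by convention.

Hierarchical clustering normalises each cell's CPA vector to sum 1
(zero-total cells excluded, logged) and agglomerates with Ward's D2
criterion on Euclidean distances (scipy's `ward`, which reproduces R's
`ward.D2` on unsquared distances).

## Monte-Carlo nulls

Enrichment draws N cells (N = observed projection size) from the
excitatory pool *without replacement* (a with-replacement flag exists),
counts the region membership, and repeats 1000 times; the 95% CI is the
2.5–97.5 percentile interval of the draws (a normal-approximation CI is
available behind a flag), and enrichment means the observed count falls
outside it. Empirical p-values carry the +1 correction,
(1 + #draws at least as extreme)/(1 + iterations), so 0 exceedances in
1000 draws reports p = 1/1001 < 0.001. Spatial restriction uses the mean
pairwise distance (median available) with a one-sided lower-tail p. On
small pools the draw frequencies converge to the exact hypergeometric law,
and when the observed set is itself a null draw the CI covers it in ≈96%
of replicates — slightly above nominal because percentile intervals of a
discrete count distribution round outward. Cell-body-area comparisons are
unpaired two-sided Mann-Whitney U tests with no multiplicity adjustment;
the number of comparisons is logged.

## The synthetic-data generator

`gen_counts` emulates the study conditions: 1231 cells, 27%/73%
population split (Bernoulli per cell), 415 planted differential genes,
log-normal library sizes (median 2×10⁵ counts, σ_log 0.35) and gamma-
Poisson (negative-binomial, shape 2) gene noise over a log-normal baseline
whose spread (σ = 2.5 over 12,000 genes) was chosen so the mean number of
detected genes per cell is ≈5.9k. Half the differential genes are binary
on/off (20–60 CPM in the enriched population, 50× lower elsewhere), half
partially penetrant (10× elevation in a Bernoulli(0.6) subset of the
enriched population over a 1–5 CPM baseline), mirroring the two observed
marker flavours. Forty gradient genes per population follow monotone
logistic profiles in a latent u ∈ [0, 1] with per-seed midpoints and
slopes (high gene-to-gene variation); their means are normalised within
the population so that grading does not create additional
between-population differential expression, keeping the planted
differential count exactly 415. Two housekeeping-style gate genes (Snap25
high everywhere, Gad1 near zero) are included with low dispersion so the
gating stage runs cleanly end to end.

`gen_spatial_cells` draws uniform positions inside a section template and
assigns CPA values: the discrete markers follow a logistic in signed
border distance (slope 0.04/µm, i.e. a ~50 µm transition; infinity gives a
hard step), gradient genes follow logistic profiles along per-gene axes
spread over the half-circle, and noise is additive Gaussian (σ = 0.008)
truncated at zero — the simplest noise respecting CPA's non-negativity,
and the truncation is what produces exact zeros and hence phenotype
indices of exactly ±1. Spill-over cells (5%) carry the opposite discrete
marker at full level with sub-gate Slc17a7 and are flagged
interneuron-like in the truth table. Projection subsets are truncated
isotropic Gaussians clipped to a nucleus; image fixtures are analytic
disks with wrap-around integer translations so phase-correlation recovery
is exact by construction.

**What the generator does not emulate:** raw reads or UMI chemistry,
doublets, batch effects, optical point-spread, 3-D tissue structure, or
the real per-gene effect-size spectrum of the BLA (no public quantitative
per-gene effect sizes exist for the 415-gene set). Passing tests therefore
demonstrate that the pipeline's operations are correct and recover planted
structure at realistic signal-to-noise — not that they would reproduce any
particular real dataset's boundaries.

## Problem sizes and reproducibility

The reproduction script and acceptance tests use the defaults above:
20 seeds for clustering/proportion recovery, 10 for the differential-gene
count, 100 random-forest replicates at n_train = 100, 500 outer × 1000
inner Monte-Carlo replicates for CI coverage, and three 1000-cell sections
for the spatial gradient. Every stochastic step draws from
`numpy.random.default_rng` seeded from a single top-level seed; igraph's
Louvain RNG is seeded per call. Identical seeds give bitwise-identical
outputs everywhere, including reports.

## Known limitations

* Louvain at low resolution can in principle merge two weakly separated
  populations; with the default planted effect sizes this was never
  observed, but much smaller effect sizes would require tuning k or the
  resolution.
* The Slc17a7 "no watershed" rule means touching somata merge; counts from
  `segment_slc17a7` are therefore a lower bound in dense fields.
* Percentile CIs on discrete Monte-Carlo draws are mildly conservative
  (coverage ≈96% at nominal 95%).
* The templates are illustrative geometry; real-atlas registration
  accuracy is out of scope.
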