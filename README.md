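# amygmap

Tools for resolving **discrete** and **graded** excitatory-neuron
heterogeneity in the basolateral amygdala complex (BLA), the way a combined
scRNA-seq + multiplexed-FISH + viral-tracing study analyses it. The package
is aimed at computational neuroscientists and quantitative biologists who
want the full analysis chain — from count matrices and segmented-cell
tables to enrichment verdicts — as tested, reusable library code, plus a
synthetic-data generator so every stage runs without any external download.

## The analysis

The BLA contains two excitatory populations that separate discretely in
transcriptome space and map onto the lateral (LA) and basal (BA) nuclei,
while expression *within* each nucleus varies smoothly along spatial
gradients. The pipeline resolves both modes:

* **scRNA-seq stage** (`amygmap.sc_pipeline`): cells under 10,000 total
  counts are excluded; counts are normalised to CPM (counts per million);
  non-neurons are rejected at Snap25 CPM < 250 and interneurons at Gad1
  CPM > 100; variable genes are selected by binned mean/dispersion
  z-scores (cutoffs 0.125 / 3 / 1); cells are embedded with PCA (10 PCs),
  clustered on a shared-nearest-neighbour graph by Louvain modularity
  maximisation (resolution 0.2 for the coarse two-way split, 0.8 for fine
  structure); cluster markers are tested with two-sided Wilcoxon rank-sum
  tests under Bonferroni control (p_adj < 0.05); and cluster robustness is
  quantified by random forests trained on small random cell subsets.
* **Spatial registration** (`amygmap.spatial_register`): six landmark
  points per section are mapped onto a template by rigid Procrustes
  (rotation + translation, **no scaling, no reflection**), cells follow the
  same transform, and LA/BA membership comes from point-in-polygon tests.
* **Image stage** (`amygmap.image_quant`): chromogenic (blur → threshold →
  watershed, 100–400 µm²), DAPI nuclei (40–200 µm², then 5 µm dilation) and
  Slc17a7 somata (75–450 µm², no watershed) segmentation; integer-pixel FFT
  phase-correlation alignment of imaging rounds; per-cell expression as
  counts-per-area, CPA = signal pixels inside the ROI / ROI pixel area.
* **Spatial statistics** (`amygmap.spatial_stats`): the per-cell
  **phenotype index**

  > (E_Cplx1 − E_Negr1) / (E_Cplx1 + E_Negr1) ∈ [−1, 1]

  (−1 for Negr1-exclusive, +1 for Cplx1-exclusive cells); winner-take-all
  phenotyping of Slc17a7-gated cells (gate 0.004 CPA); Pearson
  cell-to-cell expression correlations averaged in 100-µm distance bins,
  split by same/opposite phenotype; Ward-D2 hierarchical clustering of
  sum-to-1-normalised CPA rows.
* **Projection nulls** (`amygmap.projection_null`): 1000-iteration
  Monte-Carlo nulls — random equal-size selections from the excitatory
  pool — with 95% percentile confidence intervals for regional enrichment
  and mean-pairwise-distance spatial restriction, and Mann-Whitney U
  cell-body-area comparisons.
* **Synthetic data** (`amygmap.synthdata`): seeded generators for all of
  the above: a 1231-cell, 27%/73% two-population negative-binomial count
  simulator with 415 planted differential genes and within-population
  latent gradients; a BLA section template with a sharp Negr1/Cplx1 border,
  smooth marker gradients and interneuron-like spill-over; projection
  subsets; paired analytic disk image stacks.

## Worked example

```python
from amygmap import synthdata as sd, sc_pipeline as sc
from amygmap.containers import CountMatrix
from sklearn.metrics import adjusted_rand_score

counts, truth = sd.gen_counts(sd.ScSimConfig(seed=1))
filtered, _ = sc.qc_filter(counts)                 # <10,000-count cells out
e = sc.to_cpm(filtered)
exc = sc.gate_cell_classes(e)["excitatory"]        # Snap25/Gad1 gates
e = sc.to_cpm(CountMatrix(filtered.counts.loc[:, exc]))
genes = sc.select_variable_genes(e)
scores = sc.pca_embed(e, genes)
res = sc.cluster_graph(scores, resolution=0.2, seed=1)
print(res.n_clusters, res.sizes().to_dict())
print(round(adjusted_rand_score(truth.population.values, res.labels.values), 3))
de = sc.differential_expression(e, res.labels, 0, 1)
print(len(de.significant(0.05)))
```

prints

```
2 {0: 912, 1: 319}
1.0
415
```

i.e. coarse clustering at resolution 0.2 returns exactly two clusters
whose labels match the planted populations perfectly (adjusted Rand index
1.0), the smaller cluster holds ~26% of cells (planted 27% up to binomial
sampling), and the Wilcoxon/Bonferroni screen recovers all 415 planted
differential genes.

The same conditions drive the spatial stage:

```python
from amygmap import spatial_stats as ss
cells, _ = sd.gen_all_sections(sd.SpatialSimConfig(seed=3))
phen = ss.binarize_phenotype(cells)
print(ss.bimodality_summary(ss.phenotype_index(phen))["extreme_fraction"])
```

prints `0.784…`: ~78% of phenotyped cells sit at extreme (|index| ≥ 0.8)
values, the bimodal structure expected from a sharp LA/BA border.

There is also a CLI: `amygmap run-all --seed 1 --out report.json` executes
every stage and writes the full reproducibility report (see
`amygmap --help` for the per-stage commands).

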