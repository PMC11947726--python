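# jejumap

Breed-comparative single-cell RNA-seq analysis of the pig jejunum, built as
a tested, reusable Python library. The target setting is a three-breed
immune atlas of the small intestine — Asian wild boar (AWB), the Chinese
local Jinhua breed (JH), and the intensive Duroc breed (DU) — where the
questions are: which cell types live in the jejunum of each breed, how do
their proportions and expression programs differ, and what changed along
the domestication gradient AWB → JH → DU?

Because such atlases are rarely redistributable, the package ships a
**synthetic atlas generator with ground truth**: gamma–Poisson counts over
a lognormal baseline, six major lineages plus T/ILC/NK and plasma-cell
subtypes at the published compositions (26,246 cells: AWB = 11,929,
JH = 2,645, DU = 11,672; pooled 65.4% T/ILC/NK, 25.1% epithelial, 7.3%
plasma, …), marker-gene fold changes, mitochondrial content, damaged cells
and doublets. Every analysis stage is validated by recovering what the
generator planted.

## What's inside

| module | what it does |
|---|---|
| `jejumap.synth_atlas` | multi-breed synthetic atlas with per-cell ground truth; doublet injection |
| `jejumap.io_qc` | 10x-style MTX triplet reader/writer; simulated-doublet kNN score; QC filters (score ≥ 0.25, mito > 50%, genes < 200 or > 7,500) |
| `jejumap.cluster_annotate` | normalization, HVG, PCA, Leiden clustering; two-tier marker-panel annotation; cell-cycle scoring; cross-breed dendrogram (Newick) |
| `jejumap.composition` | bootstrapped permutation test on per-cluster proportions (log2 fold difference, FDR < 0.05, \|log2FD\| > 1.5) |
| `jejumap.scoring` | module scores with binned background controls; dot-plot panel statistics |
| `jejumap.differential` | vectorized tie-corrected Wilcoxon rank-sum DE (exact at tiny n); BH step-up; hypergeometric enrichment |
| `jejumap.domestication` | fuzzy c-means over standardized breed profiles; fuzzifier estimate; Dmin; four-pattern classification (increasing / JH-high / JH-low / decreasing) |
| `jejumap.communication` | ligand–receptor interaction means (complexes = min over subunits), cluster-label permutation p-values, top-20 selection |
| `jejumap.robustness` | cell-number and depth downsampling with pseudobulk log-CPM Pearson agreement |
| `jejumap.pipeline` | end-to-end recovery experiments wiring the above together |

## The statistics, briefly

- **Composition test.** For cluster *c* and breeds *A*, *B*:
  log2FD_c = log2(p_c^A / p_c^B) with group proportions p_c; null from
  shuffling breed labels over cells, p = (1 + #{|log2FD*| ≥ |log2FD|}) / (n_perm + 1);
  bootstrap CIs resample cells within breeds; BH across clusters.
- **Module score.** Genes are ranked by mean expression and cut into 25
  bins; each set gene draws 100 bin-matched controls;
  score(cell) = mean(set) − mean(controls) on log-normalized expression.
- **Fuzzy c-means.** Bezdek alternating optimization of
  Σᵢⱼ uᵢⱼ^m ‖xᵢ − cⱼ‖², memberships uᵢⱼ = 1 / Σₖ (dᵢⱼ/dᵢₖ)^{2/(m−1)};
  fuzzifier m from the empirical estimate
  m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134).
- **Communication.** Interaction mean = (ligand mean in source + receptor
  mean in target)/2, complexes take the minimum over subunit means, gated
  at 10% expressed fraction; permutation null over cluster labels.

## Worked example

```python
from jejumap import pipeline

res = pipeline.pooled_lineage_recovery(n_cells=4000, seed=0)
print(res.percentages.round(1))
print(f"annotation recovery: {res.recovery:.1%}")
```

prints

```
T/ILC/NK      66.1
epithelial    24.4
plasma         7.4
myeloid        2.0
annotation recovery: 98.5%
```

A 4,000-cell atlas was simulated at the published pooled composition, QC'd
(doublet score, mito fraction, gene counts), clustered with Leiden and
annotated from the marker panels; the recovered percentages sit within
sampling noise of the planted 65.4 / 25.1 / 7.3 / 1.4 — and 98.5% of cells
got their planted lineage back. The `examples/` directory has one short
script per capability (simulation, QC, annotation, composition test,
scores, DE + enrichment, domestication patterns, communication,
downsampling).

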