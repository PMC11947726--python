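# Methods

## The synthetic atlas generator

The generator emulates the structure of a three-breed pig jejunum immune
atlas at single-cell resolution. It is first-class, tested code: its
defaults *are* the study conditions every downstream validation runs under.

**Count model.** Counts are gamma–Poisson (negative binomial): for cell
*i* and gene *g*, counts ~ Poisson(Γ(1/φ, μ_ig·φ)) with overdispersion
φ = 0.4 (Var = μ + φμ²). Per-gene relative baseline means are lognormal
(μ = 0, σ = 1.5), giving the heavy right tail of depth-normalized real
data. Per-cell depth is lognormal with median 2,500 counts (σ = 0.35 on the
log scale). With the default 2,000 genes this yields ~35–40% nonzero
entries, comparable to 10x data at that gene-space size.

**Composition.** Library sizes default to the published per-breed counts
(AWB 11,929, JH 2,645, DU 11,672). Per-breed lineage weights use the
published values where printed — AWB T/ILC/NK = 83.0%, JH plasma = 32.0% —
and documented fixed fillers elsewhere; DU's weights are *derived* at
import time so that the size-weighted pooled composition reproduces the
published pooled percentages (65.4 / 25.1 / 7.3 / 1.4 / 0.6 / 0.2) exactly.
The same scheme fills the T/ILC/NK subtype weights (published CD4/CD8
percentages per breed; ILC/NK/γδ fillers) and the plasma subtype weights
(JH Type 3 = 13.1%; Type 3 absent outside JH). Every filler is a named
constant in `synth_atlas`, never a silent choice.

**Markers and programs.** Each lineage multiplies its marker panel by
`marker_fold` (default 8) and a private block of 20 unnamed "program"
genes by `program_fold` (default 4); subtypes add their own panel and
program on top. The program blocks reflect the biological fact that cell
types differ by coordinated expression programs, not only by their
classical markers — without them, one-gene subtype panels (CD4, CD8B, BLK)
would be undetectable by clustering and subtype recovery would be
meaningless. Marker and program baselines are floored at the 75th
percentile of the baseline law: canonical markers are canonical precisely
because they are robustly detected, and a fold change planted on a
one-read-per-cell gene is invisible at realistic depth.

**Mitochondrial content and artifacts.** A configurable fraction of genes
(default 0.5%) is flagged mitochondrial; the mito block is rescaled per
cell so its expected read share matches the cell's condition — 5% for
normal cells, 65% for a 2% "damaged" sub-population that exercises the
mito QC filter. Doublets (default 5%) are appended as sums of two random
cells from the same library.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: ambient RNA, batch/chemistry effects beyond
library identity, gene–gene correlation beyond the program blocks,
UMI-collision artifacts, and continuous differentiation trajectories. All
planted populations are discrete; recovery results bound pipeline behavior
under a favorable but honest noise model, not under every pathology of
real tissue.

## Quality control

Filters run in a fixed order (doublet → mito → min genes → max genes),
with each removed cell attributed to the first filter it fails, so the
report always balances. Boundary semantics are strict inequalities:
exactly 200 or 7,500 detected genes and exactly 50% mito survive. The
doublet threshold is read in the conventional direction (remove scores
**≥** 0.25); the direction is configurable.

The doublet score simulates artificial doublets by summing random cell
pairs, co-embeds observed and simulated cells in PCA space of
log-normalized counts, and converts each observed cell's simulated-neighbor
fraction q into a posterior probability with expected doublet rate ρ
(default 0.1) and simulation ratio r = n_sim/n_obs:
score = (q/r)·ρ / ((q/r)·ρ + (1−q)(1−ρ)). Under a homogeneous no-doublet
population the score concentrates near ρ, safely below the 0.25 cutoff,
while cross-lineage doublets rank far above singlets (AUC > 0.7 in tests).

## Clustering and annotation

Depth normalization targets 10,000 counts per cell, followed by log1p,
selection of the top 2,000 variable genes, z-scaling (clipped at 10), and
50-component PCA. Clustering is Leiden on the scanpy nearest-neighbor
graph (k = 15). The working resolution range is 0.5–2; the recovery
pipeline uses **2.0** because at lower resolutions the rare lineages
(myeloid 1.4%, B 0.6%, mesenchymal 0.2%) merge into the large epithelial
and T compartments and inflate their percentages. Cluster counts on
synthetic data are not pinned — only label recovery is.

Annotation scores each cluster on each panel as the mean z-scored
log-normalized marker expression over the cluster's cells and assigns the
argmax (ties break by panel order); cells inherit their cluster's label.
It is applied twice: major lineages on all cells, then the T/ILC/NK
subtype panel within the T compartment only. Compartment subclustering
re-embeds on the compartment's own top 500 variable genes at resolution
1.0: within-compartment differences ride on far fewer genes than whole-
atlas structure, and an unselected 2,000-gene space at a few hundred cells
buries them in noise.

Cell-cycle phase calls use the binned-control module score for the S and
G2M sets; a cell is G1 iff both scores are ≤ 0, otherwise the argmax.
"Geometric-mean" phrasing of phase scoring is implemented as the
arithmetic mean in log1p space (the log of a geometric-type mean),
reconciling it with the binned-control score used everywhere else.
Optional residualization removes both scores from every gene by least
squares. The cross-breed dendrogram uses correlation distance between
(breed × cell type) mean HVG profiles with average linkage, serialized as
Newick via scikit-bio.

## Composition permutation test

The 0.5-cell pseudocount enters **only** empty cluster×group cells, so
observed non-degenerate log2FDs are exact log-ratios. The p-value uses the
add-one estimator, so p is never 0 and calibration is slightly
conservative; the type-I error at α = 0.05 lands in [0.02, 0.09] under
exchangeable nulls (tested with 200 replicate datasets). "Bootstrapped"
is split by purpose: label permutation for p-values, within-group
cell resampling for CIs; the point-estimate log2FD is reported as the
headline statistic with the bootstrap mean alongside.

## Module scores

Defaults n_bins = 25, n_ctrl = 100 follow the established convention for
binned-control scores. Controls are drawn without replacement where the
bin allows; a one-gene bin keeps the gene itself as its own control
(contributing zero signal) rather than failing. The score is invariant to
adding a constant to one cell's profile and has zero expectation under
exchangeable genes. The printed inflammation list is kept verbatim,
including "PRF", which an alias map resolves to PRF1; CD103 resolves to
ITGAE the same way.

## Differential expression and enrichment

The rank-sum test is the tie-corrected normal approximation, vectorized
over genes; when both groups have ≤ 8 cells it switches to the exact null
(validated against full enumeration of assignments). log2FC compares mean
expm1-scale expression with ε = 1e-9. The DEG call uses BH-adjusted
p < 0.05 and |log2FC| > 1.5 — the absolute-value form, since the signed
variant is ambiguous in the source material; both are available. BH is the
step-up rule with monotonicity enforcement, tested against a brute-force
transcription of the definition and against statsmodels. Enrichment is the
upper-tail hypergeometric on user-supplied gene sets intersected with the
universe; no database retrieval.

## Domestication patterns

Breed profiles are per-gene mean log-normalized expression in the fixed
order AWB, JH, DU, row-standardized (population sd); zero-variance rows
are dropped. Fuzzy c-means initializes memberships as uniform random
values raised to 1/m and normalized — the tilt scales with the fuzzifier
so centroid weights u^m keep an O(1) spread at any m. At small m this is
the classic random init; at large m memberships start and stay near-flat,
matching the known m → ∞ limit. Initializing centroids on data points
instead creates singular fixed points (a centroid locked onto one point)
at large m. Iteration stops on membership stability or objective
stability; the latter is what terminates in the large-m regime, where the
objective Σ u^m d² is numerically flat.

With only D = 3 conditions the empirical fuzzifier estimate is large
(m ≈ 3.8 at N = 1000), which makes memberships very soft: under the
conventional 0.5 core-membership threshold few genes qualify. The pattern
machinery is therefore exercised in tests at a moderate m = 1.5; the
estimate remains the default and the choice is the user's. c = 9 is the
default cluster number, with the Dmin table (minimum pairwise centroid
distance per c) as an advisory diagnostic only.

Pattern rules on the centroid (a, b, c) over (AWB, JH, DU): increasing iff
a < b < c; decreasing iff a > b > c; JH-high iff b > max(a, c); JH-low iff
b < min(a, c); exact ties leave the cluster unclassified (measure-zero on
z-scored profiles). A gene is classified only if its best-cluster
membership reaches 0.5 **and** the DEG evidence matches: JH-high/JH-low
need the call in both JH comparisons; monotone patterns need at least one
JH comparison with slope-consistent sign.

## Communication

The interaction statistic is mean-based (entity mean per cluster,
complexes take the minimum over subunit means, pair value is the average
of ligand-in-source and receptor-in-target), with a one-sided ≥-tail
permutation p over cluster labels and the add-one estimator. Gated triples
(either entity expressed in ≤ 10% of its cluster) are reported as
undefined (NaN), never as zero. Top-k selection filters p < 0.01, ranks by
interaction mean, and breaks ties lexicographically by pair name. The pair
fixture uses the printed symbols verbatim (including HLA-DRA) with the
alias map bridging to the synthetic universe.

## Downsampling robustness

Cell-number mode draws without replacement per group; depth mode thins
each cell above the target to exactly the target total by a multivariate
hypergeometric draw over its gene counts (per-gene expectations stay
proportional; totals are exact). Agreement is Pearson r between per-group
pseudobulk vectors after CPM + log1p; the raw-sum correlation is reported
alongside. Defaults: 2,000 cells per group or 8,172 / 6,300 counts per
cell, 5 replicates.

## Problem sizes in the validation runs

The test suite and the acceptance script size their simulations for a
single CPU: the downsampling check runs on the full 26,246-cell default
atlas; the pooled lineage recovery on ~10,000 cells; the AWB library on
~10,000; the JH library on ~2,600; the JH T compartment on 3,000; the JH
plasma compartment on 800 cells. The three smallest experiments are
replicated three times and averaged in the acceptance script, because at a
few hundred cells per population the multinomial draw alone contributes
1–1.5 percentage points of noise. Unit and property tests run at a few
hundred to a few thousand cells.

## Known limitations

- Annotation is forced-choice argmax: a cluster with no genuine signal for
  any panel still receives a label. Margin-based abstention is not
  implemented.
- Cross-library integration is reduced to optional per-batch mean
  centering of the embedding; the synthetic data is single-batch, so
  integration quality is untested here.
- The composition test models one library per breed; biological replicate
  variance (mixed models, Dirichlet-multinomial) is out of scope.
- The Wilcoxon exact path enumerates only tiny groups; everything else is
  asymptotic with tie correction.
- GO/KEGG term databases are user fixtures; enrichment results depend
  entirely on the sets supplied.
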