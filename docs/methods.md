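# Methods

This note documents the models and procedures implemented in `sncausal`,
the assumptions behind them, the tunable parameters that matter, and the
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and containers

Counts are genes × cells sparse integers (`CountMatrix`), the 10x
deposition orientation; per-cell metadata carries sample/donor, cell
type, genotype (NT/HD), treatment (vehicle/T&B), region, age, sex,
batch, CAG repeat length, library size, and mitochondrial fraction.
Matrices used for Bayesian network learning are cells × genes
(observations × variables), the scikit-learn convention.

## QC and normalization

Nuclei are kept when 200 ≤ detected genes ≤ 6000 (both bounds inclusive)
and mitochondrial read fraction ≤ 2%. These are conventional snRNA-seq
nuclei filters: nuclei have low ambient mito content, so even 2% marks
ruptured or debris-laden droplets. Normalization is
`ln(1 + s·c/total)` with scale factor `s = 10⁴` — the standard scaled
log transform; it is invariant to per-cell sequencing depth and keeps
zeros at zero.

Genes enter network analyses only when detected (count ≥ 1) in at least
25% of all cells (inclusive), which removes the extremely sparse genes
that dominate droplet data and would otherwise discretize into a single
occupied level.

## Differential expression

Two-sided Wilcoxon rank-sum tests, per gene, on log-normalized
expression; a gene is tested when detected in ≥ 25% of *either* group.
When both groups have ≤ 25 cells and the pooled sample is tie-free the
exact permutation null is used; otherwise the normal approximation with
tie and continuity corrections (both via `scipy.stats.mannwhitneyu`).
Fold changes are `log2` of the ratio of mean de-logged expression
(`mean(expm1(·))`, pseudocount 10⁻⁹) — conventions differ between tools
(ln vs log2); this package standardizes on log2 and says so in the
output header. BH adjustment spans tested genes only; significance
defaults to adjusted p < 0.05 (configurable, since the adjustment
convention for this kind of contrast is tool-dependent).

## Co-expression modules

Signed adjacency `a_ij = ((1 + cor(i,j))/2)^β` on log-normalized
expression of filter-passing genes, control (NT) cells only, with cells
subsampled to a 10,000-cap (seeded) before the gene–gene correlation for
tractability. β is selected as the smallest candidate whose signed
scale-free fit reaches R² ≥ 0.8; the fit is the squared correlation of
log10(frequency) vs log10(mean connectivity) over 10 connectivity bins,
sign-penalized when the slope is positive. When no candidate reaches
0.8 the best-fitting candidate is used, **restricted to powers whose
network keeps mean connectivity ≥ 1**: at very high powers nearly all
adjacencies vanish and the log-log fit is computed on noise, so apparent
scale-free behavior there is spurious. Without this floor the fallback
can select a near-empty network in which no modules survive.

Topological overlap is
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with unit
diagonal. Modules come from average-linkage clustering of `1 − TOM`
with a **static cut** (default height 0.99) — chosen over dynamic
hybrid cutting because it is deterministic and directly testable —
followed by assignment of clusters below 30 genes to the unassigned
label 0 and iterative merging of modules whose eigengenes correlate
above 0.75. Labels are renumbered by decreasing size. Note the cut
height is a genuine tuning parameter: clusters whose join height falls
below it will not separate, so strongly separated but mutually
correlated blocks may require a lower cut.

Eigengenes are unit-variance first-principal-component scores of the
standardized module submatrix, sign-fixed so mean member correlation is
non-negative. kME is the Pearson correlation of each gene with each
eigengene. Module–trait association uses Pearson r against one-hot
cell-type indicators with the Student asymptotic two-sided p
(`t = r·sqrt(n−2)/sqrt(1−r²)`), computed through the regularized
incomplete beta function. Module–DEG enrichment is the inclusive
upper-tail hypergeometric probability over the analyzed-gene universe.

## Discrete Bayesian networks

Features for a cell type are the union of its significant DEGs and the
genes of the module most positively correlated with that cell type. In
the orchestrated pipeline the union is capped at 50 features (module
genes ranked by kME, then DEGs by adjusted p) so that bootstrap learning
stays tractable at desk scale; the cap is configuration.

Expression is discretized per gene into 3 equal-width intervals spanning
[min, max] (half-open, last closed); bins are computed once on the full
per-cell-type data — both conditions pooled — so NT and HD networks are
learned on a common coding and bootstrap replicates are comparable.
Three levels is the coarsest discretization that can still represent
monotone and non-monotone dependence; it is also a pragmatic answer to
droplet sparsity.

Scoring is BDeu with imaginary sample size `iss = 1`:
for each node i with r_i levels and q_i parent configurations,
`Σ_j [lnΓ(α_ij) − lnΓ(α_ij + N_ij)] + Σ_jk [lnΓ(α_ijk + N_ijk) − lnΓ(α_ijk)]`
with `α_ijk = iss/(r_i q_i)`. This prior family is the one that makes
Markov-equivalent DAGs score identically (verified exhaustively in the
tests over all 25 three-node DAGs).

Search is plain greedy hill climbing from the empty graph over single
arc additions, deletions, and reversals, with no priors, restarts, or
tabu list. Ties are broken deterministically (add < delete < reverse,
then parent label, then child label) and family scores are cached by
(child, parent set), so a rerun on identical data returns the identical
graph. Moves must keep the graph acyclic; an optional in-degree cap is
available (default unlimited).

Model averaging draws 200 bootstrap replicates of ⌈0.5·n⌉ rows
**without replacement** (the configurable alternative resamples with
replacement); each replicate reuses the full-data bins and contributes
its learned arcs to per-pair strength (presence frequency, either
direction) and per-ordered-pair direction (orientation frequency among
present). The averaged network keeps pairs with strength ≥ 0.85 and
orients by direction ≥ 0.5; an exact 0.5/0.5 split is oriented
lexicographically and flagged. Because pairs are thresholded
independently the result can be cyclic; cycles are repaired by dropping
the weakest-strength arc per cycle, loudly.

Condition networks are merged with node/edge provenance (NT / HD /
both); where an edge exists in both, the NT strength is kept as the
weight. Key drivers are hubs — out-degree strictly greater than 10 —
and connectors: non-hub nodes X with hubs H1 ≠ H2 such that H1→X and
X→H2 (the directed-path reading; an undirected-adjacency reading would
admit more connectors and is intentionally not the default).

Skeleton F1 is the accuracy measure for recovery experiments because
orientation is identifiable only up to the Markov equivalence class.

## Rescue analysis

Three Wilcoxon contrasts per cell type: genotype (case+vehicle vs
ctrl+vehicle), treatment (case+treated vs case+vehicle), residual
(case+treated vs ctrl+vehicle). Genes significant in both genotype and
treatment contrasts are classified by the signs of their Z-scored log2
fold changes (population-SD Z-scores over each table's tested genes):
opposite signs ⇒ rescued, same signs ⇒ exacerbated, an exactly zero
Z ⇒ unchanged. The per-cell-type rescue fraction is
rescued/(rescued+exacerbated), defined as 0 when nothing is classified
(no evidence of rescue). The DEG-count reduction is
`log2((n_residual + 1)/(n_vehicle + 1))`; the unit pseudocount keeps the
ratio finite when a treatment abolishes all DEGs.

Two properties of this estimator are worth knowing. First, non-rescued
genes have no treatment effect and therefore rarely enter the
doubly-significant overlap, so at intermediate planted rescue fractions
the estimate saturates near 1 (the overlap is nearly all rescued genes);
it is monotone in the planted fraction, and accurate at the endpoints.
Second, with a near-empty overlap (planted fraction 0) the estimate
rests on a handful of false positives; the reported overlap size should
always be read alongside the fraction.

## CAG regression

Counts are summed per (donor, region) pseudo-sample after the cell-type
filter, log-normalized per sample (`ln(1 + 10⁴·c/total)`), and each
gene scaled to zero mean / unit variance across samples. Per gene,
ordinary least squares regresses scaled expression on [intercept, CAG,
age, sex, batch dummies, region dummies] (treatment coding, first level
reference), with a two-sided t-test on the CAG coefficient and BH
adjustment. Rank-deficient designs raise an explicit error naming the
aliased columns. Plain OLS with per-gene t-tests is used rather than
moderated statistics; an optional light empirical-Bayes variance
shrinkage (residual variances pooled toward their mean with a prior
weight of 4 df) is available behind a flag for very small designs.
"Significant CAG coefficient" means BH-adjusted p < 0.05 by default.
The OPC/OL quadrant classification crosses the two significance flags
(OPC_only / OL_only / both / neither) with the coefficient sign pattern;
"+/+" is the both-positive (upper-right) quadrant.

Because the per-gene scaling divides by each gene's cross-sample SD —
which itself grows with the CAG effect — fitted coefficients are a
saturating, monotone transform of the planted slopes; the
planted-vs-fitted Pearson correlation is the recovery measure.

## Synthetic-data generator

The generator is the package's test bed; its defaults are the study
conditions the tests assume.

Latent model, per cell and gene, on the natural-log scale:

* **Baselines**: background genes `N(0, 1.5)` log-weights; module, DAG,
  DEG, and CAG genes `N(1.2, 0.4)` (typical counts of a few per cell at
  5,000-UMI depth) — network-relevant genes in real data are
  moderately-to-highly expressed, and they must survive the 25%
  detection filter. Weights are normalized per cell to relative rates.
* **Modules**: each of the (default 4) modules of 50 genes shares a
  per-cell latent factor (loading 1, SD 1); the factor mean is shifted
  +1 in the module's anchor cell type, which is what makes eigengenes
  correlate with cell-type traits.
* **Causal DAG**: (default 20) dedicated genes follow linear Gaussian
  structural equations `child = 0.8·Σ parents + ε` along a random DAG
  with ≤ 3 parents per node, with each node standardized to unit
  marginal variance. Standardization matters: without it multi-parent
  chains accumulate variance multiplicatively and the exponentials of
  those heavy-tailed log values dominate the per-cell rate normalizer,
  leaking condition-dependent artifacts into every other gene. HD cells
  use a subset of the NT edge set (default 30% of edges removed).
* **DEGs**: (default 100) genes carry ±deg_lfc (default 1.5) log2
  effects in HD cells, converted to natural log before count sampling.
  Effects alternate up/down in pairs, and the down gene of each pair
  gets 2^lfc times the up gene's baseline weight, so the total
  expression mass is exactly preserved under the effects — without this
  balance, library-size normalization converts the net DEG mass into a
  small systematic shift of every other gene, which a rank test detects
  at large n. A planted fraction of DEGs (default 0.8) has its effect
  set to zero in HD+treated cells ("rescue").
* **CAG**: (default 50) genes receive `slope·(CAG − 20)` with per-gene
  slopes drawn ± uniformly up to 0.02 natural-log units per CAG repeat.
  Twelve donors (three per genotype × treatment arm; NT CAG 18–23, HD
  CAG 45–70, alternating sex, paired batches) and two regions give 24
  pseudo-samples.
* **Mitochondria**: 1% of genes are designated mito; each cell draws a
  target mito fraction from Beta(2, 248) (mean ≈ 0.8%), except a 5%
  "bad cell" fraction drawing Uniform(0.03, 0.10) — so the 2% QC filter
  has true positives.
* **Counts**: `NB(mean = L_c·exp(latent), dispersion θ = 2)` with
  variance `μ + μ²/θ`; per-cell library sizes are
  Lognormal(ln 5000, 0.3).

All randomness flows from the design seed through named
`SeedSequence` substreams (truth / latent / counts / mito), so identical
designs give bit-identical datasets and partial re-runs are stable.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects on expression (batch labels exist only as regression
covariates), spliced/unspliced structure, gene-length bias, and any
nonlinearity in the CAG–expression relationship. Passing tests
therefore demonstrate correctness of the statistical machinery under a
negative-binomial/linear-Gaussian world, not robustness to those real
artifacts.

### Observation noise and structure recovery

The count layer attenuates the DAG signal: a parent–child latent
correlation of ~0.6 falls to ~0.3 in log-normalized counts at these
expression levels and θ = 2, and the 0.85 bootstrap consensus then
trades recall for precision. Structure-recovery experiments are
therefore run on the discretized latent structural layer — the
generative stand-in the discrete learner addresses — where the
200×50% bootstrap at 0.85/0.5 recovers planted 20-node skeletons with
F1 well above 0.7 across draws; the end-to-end count-based F1 is
reported alongside (typically 0.4–0.7, depending mostly on the density
of the drawn DAG) so the attenuation is visible rather than hidden.

## Problem sizes

Test and acceptance runs use desk-scale data chosen to finish quickly on
one CPU while keeping every estimate well-identified: 2,000-gene /
600-cell DEG experiments, 1,000-cell module recovery, 2,000-cell
structure recovery with the full 200-round bootstrap, 600 cells per arm
for rescue, and 24 pseudo-samples for CAG regression. The orchestrated
smoke pipeline runs the complete default design (2,000 genes, 4 cell
types × 4 arms × 150 cells) with a 50-round bootstrap.

## Known limitations

* The static tree cut requires the cut height to sit above within-module
  join heights; module structure joining below the default 0.99 needs a
  lower cut.
* Hill climbing returns a local optimum; no restarts are attempted by
  design (plain hill climbing is the specified search).
* The rescue-fraction estimator saturates at intermediate planted
  fractions (see above) — it measures discordance among genes that
  respond to treatment, not the proportion of disease genes rescued.
* Pseudobulk regression treats donors as independent samples; repeated
  regions per donor are modeled only through the region covariate, not
  as a random effect.
* CAG length is confounded with genotype by construction in the default
  donor panel, as it is in real case/control cohorts; the regression
  does not attempt to separate the two.
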