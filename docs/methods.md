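# Methods

## Scope and data model

`msbr` implements a methylation-first subgrouping framework for tumor
cohorts. All computations run on three in-memory containers: a
`BetaMatrix` (probe × sample methylation levels in [0, 1], NaN for
missing, with sample group labels), a `ProbeAnnotation` (probe → position,
strand, gene, TSS; 0-based coordinates), and plain pandas objects for
expression, proportions, and clinical tables. Everything the pipeline
consumes can be produced by the generators in `msbr.synthetic`, which also
return the planted ground truth, so each stage is testable without any
external download.

## Differential methylation

Promoter windows run 2000 bp upstream to 500 bp downstream of the TSS,
oriented by strand; coordinates are 0-based and the windows half-open, with
the TSS itself included on both strands. Probes missing in more than half
the samples are removed (strictly greater than, so exactly 50 % missing
survives). Imputation replaces each missing entry by the mean of the
k = 10 nearest probes (Euclidean distance over commonly observed samples,
ties broken by probe order); k = 10 is the common choice for methylation
arrays. The per-probe test is Student's t with pooled variance (a Welch
flag exists); probes with zero variance in both groups receive p = 1 so
that Benjamini–Hochberg stays well defined. A probe is differential iff
|β̄_case − β̄_control| ≥ 0.2 (inclusive) and BH-FDR < 0.05; a gene is
differential iff at least one of its promoter probes is.

## Co-methylation network

The network is unsigned: a_ij = |cor|^β. The soft power is the smallest
β ∈ 1..20 whose scale-free fit R² (log-frequency on log-connectivity over
10 bins) reaches 0.85, falling back to the argmax when none does; on small
block-structured inputs the scale-free criterion is close to
uninformative, and the analysis drivers use the conventional unsigned
default β = 6 where they fix the power. Topological overlap follows the
standard formula with unit diagonal. Modules come from average-linkage
clustering of 1 − TOM with a static cut at 0.99 of the maximum merge
height; clusters below `min_module_size` become grey. A static cut was
chosen over the dynamic hybrid tree cut for determinism at desk scale; the
dynamic cut is a possible extension. Module size floor defaults to 30
(array-scale convention); the pipeline preset uses 8 because the synthetic
cohorts plant modules of 15–30 genes.

## KMscore and key genes

Pathway enrichment is the one-sided hypergeometric upper-tail test with no
multiplicity correction, because downstream selection thresholds raw
p < 0.05. KPGenes is the union of genes of all significant pathways; an
optional flag restricts this union to pathways marked cancer-related.
KMscore_i = |KPGenes ∩ Gene_i| / |Gene_i| over non-grey modules (grey is
unassigned by definition and is excluded from scoring). Key modules must
score strictly above the mean and at or above the upper quartile; the
quartile uses inclusive linear interpolation (numpy's default). When no
module passes — for example when all scores tie — the top-scoring module is
selected with a warning, so the downstream intersection is never
structurally empty. Key genes are the intersection of key-module genes
with the classifier's feature genes.

## Feature selection and classification

Collinear probes are pruned greedily in descending-variance order at
|r| > 0.9, keeping one representative per near-duplicate group. The
Boruta-style selector appends, per iteration, three independently
column-permuted shadow copies of every feature, fits a random forest
(unlimited depth, impurity importances), and scores a hit when a real
feature's importance strictly exceeds the maximum shadow importance.
Decisions use the two-sided binomial test at p = 0.5, applied as its two
one-sided halves with Bonferroni correction over the input features;
features that can no longer reach either decision bound by the iteration
cap are moved to tentative immediately. Two design points matter and were
chosen after observing failure modes of the naive variant:

- **The forest always contains every feature.** If resolved features leave
  the design, the max-shadow bar is taken over ever fewer shadows and
  sinks, and features whose apparent relevance is dataset luck (chance
  |r| with the labels of up to ~0.3 at n = 100) eventually clear it.
- **Several shadow copies per feature** raise the bar further; with three
  copies the selector confirms a planted label-identical feature while
  confirming zero of twenty noise features in ≥ 95 % of runs, and confirms
  nothing on pure noise.

A `rough_fix` helper resolves tentative features post hoc by comparing
each one's median importance against the median of the per-iteration
max-shadow thresholds, mirroring common Boruta practice; the pipeline uses
confirmed plus rough-fixed features (with a single shadow copy and 200
trees — in the dense-signal regime of ~100 correlated truly differential
probes, per-feature importance is diluted by roughly 1/p, and the hit
probability of a true probe approaches the probability that any tree uses
it at all, so more trees and the post-hoc fix recover sensitivity that the
conservative defaults trade away).

The classifier is a linear SVM (C = 1; RBF behind a flag) on standardized
inputs. The 7:3 split is stratified; cross-validation is stratified
10-fold on the training side; AUC is the rank-based (Mann–Whitney) form
with half-credit for ties, which equals trapezoidal ROC integration.

## Subgrouping

Samples are clustered on key-gene promoter-mean beta values by Ward
linkage on Euclidean distance (complete/average behind flags). The cluster
count k ∈ 2..6 is a majority vote of five deterministic internal validity
indices: mean silhouette, Calinski–Harabasz, Davies–Bouldin (inverted),
Dunn, and the Hubert–Levin C-index (inverted); ties go to the smaller k.
A three-index panel (silhouette, CH, DB) was tried first and systematically
merged graded, nearly collinear subgroups — three ordered methylation
levels on one gene axis — because silhouette and DB reward compactness
over separation there; Dunn and the C-index resolve exactly that geometry,
and the five-index vote is closer in spirit to the NbClust-style consensus
it stands in for. The t-SNE embedding is for plots only and never feeds a
decision.

## Deconvolution and immune scores

Marker genes per cell type come from one-vs-rest Wilcoxon rank-sum tests
on log1p expression with BH correction (FDR < 0.05 and log-fold-change
≥ 1); the signature column is the per-type sum of expression over the
union of markers. Deconvolution standardizes the signature matrix by its
global mean and standard deviation — a single affine map that preserves
relative column scales, hence proportions — and each bulk profile per
sample, then fits linear ν-SVR for ν ∈ {0.25, 0.5, 0.75} (C = 10), keeps
the lowest-RMSE fit, clips negative coefficients, and renormalizes onto
the simplex. Noiseless mixtures of the signature are recovered to < 0.02
per proportion. CYT is the linear-scale arithmetic mean of GZMA and PRF1
per sample (log-scale behind a flag). Methylation specificity normalizes
per-gene subgroup mean betas into a distribution and computes Shannon
entropy; a gene is subgroup-specific iff its entropy is below the 0.25
quantile of candidates and its Kruskal–Wallis p < 0.05. All-zero genes
receive the maximal entropy log2(k) and are never flagged.

## Survival and cohort statistics

Kaplan–Meier curves and the multi-group log-rank test come from lifelines;
chi-square (no continuity correction) and Kruskal–Wallis (tie-corrected)
from scipy. All-identical values short-circuit Kruskal–Wallis to
H = 0, p = 1 rather than erroring. The summary builder reports per-subgroup
sizes, stage proportions, median CYT, mean cell-type proportions,
TILs-type proportions, and median checkpoint-gene expression (defaults
PDCD1/CD274, configurable); no multiple-testing correction is applied
across summary panels by default (a BH flag exists).

## Synthetic cohorts: what is emulated, and what is not

`generate_cohort` plants k subgroups among the tumors. The 30 key genes
form planted module 0: each carries three promoter probes whose Beta-mean
is shifted by ±delta_beta (sign alternating by gene, so hyper- and
hypomethylation both occur) scaled by the graded subgroup multiplier
1 − 0.6·s/(k−1). The grading keeps every key probe differential in the
pooled tumor-vs-normal comparison (|mean shift| ≥ 0.7·delta_beta ≥ 0.2 at
the default delta_beta = 0.3) while separating any two subgroups by
≥ 0.6·delta_beta/(k−1) per gene; because all key genes share one subgroup
pattern, they co-methylate into a single module across tumors — the same
mechanism that makes them subgroup-informative. Additional planted modules
are decoys: truly differential (uniform shift across subgroups) but
co-methylated only through a per-module latent factor (load 0.06 on the
Beta mean, centered within tumor and normal groups so group means stay
unbiased). An earlier design with several distinct subgroup-response
patterns inside the key block was abandoned: with k = 2, any two
subgroup-informative genes are ±perfectly correlated through the subgroup
structure itself, so distinct modules inside the key block are
unrecoverable by an unsigned network in principle, not merely in practice.

Noise is Beta-distributed around the per-sample mean with concentration
beta_noise = 50 (per-probe sd ≈ 0.07 at β = 0.5), roughly matching the
spread of HM450K beta values across tumors; missingness is missing
completely at random (the mechanism in real level-3 data is
uncharacterized, so MCAR is an explicit assumption). Expression is a
five-cell-type mixture (T, B, epithelial, macrophage, stromal) with
disjoint marker blocks, Dirichlet proportions whose center depends on the
subgroup (subgroup 0 immune-enriched, subgroup 1 epithelial-enriched),
and GZMA/PRF1/PDCD1/CD274 reserved as cytotoxic-compartment genes so the
CYT score and checkpoint comparisons have planted correlates. Survival
times are exponential per subgroup hazard with independent uniform
censoring; the censoring bound solves
(1 − e^{−h b})/(h b) = censor_rate by bisection. T/N/M stages are drawn
from subgroup-skewed multinomials.

Not emulated: probe-type chemistry (Infinium I/II), batch effects,
copy-number contamination of beta values, read-count noise models for
expression, informative censoring, and spatial/histological structure.
Passing tests on these cohorts therefore shows that the pipeline recovers
the statistical structure it targets (mean shifts, correlation blocks,
mixtures, proportional hazards) at realistic effect sizes and desk-scale
n — not that it is robust to the artifacts listed above.

## Problem sizes and numerical choices

The presets use 40 (k = 2) or 48 (k = 3) tumors, 20 normals, 500 probes,
30 key genes, delta_beta = 0.3 and 5 % missingness — large enough that
every stage operates away from degenerate regimes, small enough that a
full pipeline run takes seconds. Determinism: every stochastic operation
takes an explicit seed; hierarchical clustering, the index vote (ties to
smaller k), module naming (size rank), collinearity pruning
(variance-ordered, stable sorts), and label ordering (cluster size) are
all tie-broken explicitly. Degenerate inputs either raise with the
offending identifiers (constant genes in the network, unknown strands,
singleton classes) or short-circuit to the documented neutral value
(zero-variance t-test p = 1, all-identical Kruskal–Wallis H = 0).

## Known limitations

- The static tree cut cannot split nested modules the way the dynamic
  hybrid cut can; at array scale it will under-split.
- The Boruta variant tests hit counts, not the original importance
  Z-scores; with heavily correlated feature groups its confirmed set
  depends on forest size (see above), and the rough fix trades a small
  false-positive risk for sensitivity.
- Deconvolution assumes the bulk is a nonnegative linear mixture of the
  signature columns after a global affine transform; strongly
  platform-shifted signatures would need renormalization the module does
  not attempt.
- The entropy specificity score approximates quantitative
  differentially-methylated-region callers only in intent: it flags
  concentration of methylation in few subgroups, not genomic-region
  structure.
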