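# msbr — methylation-driven immune subgrouping of luminal breast cancer

Luminal (hormone-receptor-positive) breast cancer is the most common and
most heterogeneous group of breast tumors: patients with nominally the same
PAM50 subtype (luminal A or B) differ widely in survival and in how much
their tumors are infiltrated by immune cells. `msbr` implements a
DNA-methylation-driven framework for splitting a luminal cohort into
immune-relevant subgroups and characterizing them, exercised end-to-end on
synthetic cohorts with planted structure so every stage can be scored
against a known answer.

The pipeline, stage by stage:

1. **Differential promoter methylation.** HM450K-style beta values
   β ∈ [0, 1] are restricted to strand-oriented promoter windows
   (2000 bp upstream to 500 bp downstream of the TSS), QC-filtered
   (probes with > 50 % missing beta values dropped), completed by
   k-nearest-neighbor imputation over probe rows, and tested probe-by-probe
   with Student's t-test. A site is differential when
   |β̄_case − β̄_control| ≥ 0.2 and Benjamini–Hochberg FDR < 0.05; genes
   inherit the flag from their promoter probes.
2. **Co-methylation modules.** A weighted gene network with unsigned
   adjacency a_ij = |cor(g_i, g_j)|^β (soft power β from the scale-free
   topology criterion), topological overlap
   TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
   average-linkage clustering of 1 − TOM with a static cut; modules are
   named by size with the conventional WGCNA colors, small clusters become
   "grey".
3. **Key-module scoring.** Pathways are tested by the one-sided
   hypergeometric test; with KPGenes the union of genes of all significant
   pathways (raw p < 0.05), each module i receives
   KMscore_i = |KPGenes ∩ Gene_i| / |Gene_i|. Modules scoring strictly
   above the mean and at or above the upper quartile of scores are the key
   modules.
4. **Feature selection and classification.** Differential probes are pruned
   for collinearity (|r| > 0.9, variance-ordered greedy), passed through a
   Boruta-style all-relevant selection against permuted shadow features,
   and evaluated with a linear SVM (stratified 10-fold CV on a 70 %
   training split, rank-based AUC on the held-out 30 %).
5. **Key genes and subgrouping.** Key genes = key-module genes ∩ feature
   genes. Samples are clustered on key-gene promoter-mean beta values by
   Ward-linkage hierarchical clustering; the cluster count is a majority
   vote of five internal validity indices.
6. **Immune characterization.** A cell-type signature matrix is built from
   labeled single cells by one-vs-rest Wilcoxon marker testing; bulk
   profiles are deconvolved by linear ν-SVR onto the cell-type simplex.
   Cytolytic activity CYT = (GZMA + PRF1)/2 per sample; subgroup-specific
   methylation is flagged by a Shannon-entropy criterion. Subgroups are
   compared by Kaplan–Meier/log-rank, chi-square, and Kruskal–Wallis tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on two synthetic
cohorts — a two-subgroup ("luminal A"-like, 40 tumors / 20 normals) and a
three-subgroup ("luminal B"-like, 48 tumors / 20 normals) preset, each with
500 probes, 30 planted key genes, and 5 % missing beta values:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_differential_methylation.py
python analysis/03_subgroup_pipeline.py
python analysis/04_immune_deconvolution.py
python analysis/05_cohort_comparisons.py
```

Output of a full run (seed 11):

```
luminal_a: 111/500 differential sites -> 44 differential genes
luminal_b: 101/500 differential sites -> 44 differential genes
luminal_a: k=2 (planted 2), ARI=1.0, 27 key genes, held-out AUC=1.0
luminal_b: k=3 (planted 3), ARI=1.0, 27 key genes, held-out AUC=1.0
luminal_a: deconvolved 40 samples into 5 cell types (mean reconstruction RMSE 0.079);
           median CYT 3.23; 7/27 key genes subgroup-specific
luminal_a: log-rank p=6.69e-02; CYT Kruskal-Wallis p=6.30e-08
  subgroup 0: n=20, median CYT=5.42
  subgroup 1: n=20, median CYT=0.79
```

Reading this: both cohorts recover exactly the planted number of subgroups
with a perfect adjusted Rand index against the planted labels; the key-gene
set (27 of 30 planted) comes entirely from the planted key module; the
tumor-vs-normal classifier separates perfectly on held-out samples; and the
immune-enriched subgroup (planted with a high cytotoxic T-cell fraction)
shows a ~7-fold higher median cytolytic activity score, strongly significant
by Kruskal–Wallis. Tables land under `results/<cohort>/`.

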