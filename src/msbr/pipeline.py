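"""End-to-end methylation subgrouping pipeline.

Chains the stages: promoter/QC/imputation -> differential calling ->
co-methylation modules -> pathway enrichment and KMscore key-module
selection -> collinearity pruning, Boruta and SVM evaluation -> key-gene
intersection -> hierarchical subgrouping with data-driven cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import comethylation, features, kmscore, methylation, subgroup
from .methylation import BetaMatrix, ProbeAnnotation
from .synthetic import PathwayCollection

__all__ = ["MSBRParams", "MSBRResult", "run_msbr"]


@dataclass(frozen=True)
class MSBRParams:
    """Desk-scale defaults for the synthetic cohorts.

    ``min_module_size`` is far below the array-scale WGCNA convention of 30
    because the synthetic cohorts plant modules of ~10 genes.
    """

    min_abs_bd: float = 0.2
    max_fdr: float = 0.05
    knn_k: int = 10
    min_module_size: int = 8
    cut_height: float = 0.99
    r_max: float = 0.9
    boruta_trees: int = 200
    boruta_max_iter: int = 40
    boruta_shadows: int = 1
    split_ratio: float = 0.7
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    k_folds: int = 10


@dataclass
class MSBRResult:
    differential: pd.DataFrame
    differential_genes: set[str]
    partition: comethylation.ModulePartition
    km_table: kmscore.KMScoreTable
    boruta: features.BorutaResult
    classifier_eval: features.ClassifierEval
    key_genes: kmscore.KeyGeneSet
    assignment: subgroup.SubgroupAssignment
    vote_table: pd.DataFrame


def run_msbr(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    pathways: PathwayCollection,
    seed: int = 0,
    params: MSBRParams = MSBRParams(),
    k: int | None = None,
) -> MSBRResult:
    """Run the full subgrouping pipeline on a tumor/normal beta matrix.

    ``beta.sample_groups`` must label samples "tumor"/"normal". When ``k``
    is None the cluster count is chosen by the validity-index vote.
    """
    tumor_ids = [s for s, g in beta.sample_groups.items() if g == "tumor"]
    normal_ids = [s for s, g in beta.sample_groups.items() if g == "normal"]
    if not tumor_ids or not normal_ids:
        raise ValueError("sample_groups must contain both tumor and normal samples")

    # --- preprocessing: promoter restriction, QC, imputation -------------
    promoters = methylation.promoter_probes(annotation)
    m = beta.subset_probes(promoters)
    m = methylation.filter_missingness(m)
    m = methylation.knn_impute(m, k=params.knn_k)

    # --- differential calling --------------------------------------------
    diff = methylation.call_differential(
        m, tumor_ids, normal_ids,
        min_abs_bd=params.min_abs_bd, max_fdr=params.max_fdr,
        annotation=annotation,
    )
    diff_genes = methylation.sites_to_genes(diff)
    if not diff_genes:
        raise ValueError("no differential genes; nothing to subgroup")

    # --- co-methylation modules over differential genes (tumors) ---------
    gene_mat = methylation.gene_promoter_matrix(m, annotation, genes=diff_genes)
    gene_mat_tumor = gene_mat[tumor_ids]
    power = comethylation.pick_soft_threshold(gene_mat_tumor)
    partition = comethylation.detect_modules(
        gene_mat_tumor, power,
        min_module_size=params.min_module_size, cut_height=params.cut_height,
    )

    # --- enrichment + KMscore key modules --------------------------------
    enr = kmscore.enrich_pathways(diff_genes, pathways)
    km_table = kmscore.compute_kmscores(partition, enr, pathways)
    km_table = kmscore.select_key_modules(km_table)

    # --- feature selection and classification over differential probes ---
    diff_probes = diff.loc[diff["is_differential"], "probe_id"].tolist()
    probe_mat = m.values.loc[diff_probes]
    kept = features.prune_collinear(probe_mat, r_max=params.r_max)
    labels = pd.Series(beta.sample_groups).reindex(m.sample_ids)
    plan = features.make_split(labels, ratio=params.split_ratio, seed=seed)
    boruta = features.boruta_select(
        probe_mat.loc[kept, plan.train_ids], labels.loc[plan.train_ids],
        n_trees=params.boruta_trees, max_iter=params.boruta_max_iter,
        shadows_per_feature=params.boruta_shadows, seed=seed,
    )
    selected_probes = boruta.confirmed + features.rough_fix(boruta)
    if not selected_probes:
        selected_probes = kept
    ev = features.train_eval(
        probe_mat, labels, selected_probes, plan, k_folds=params.k_folds, seed=seed
    )
    gene_of = annotation.gene_of_probe()
    feature_genes = set(gene_of.loc[selected_probes])

    # --- key genes and subgrouping ---------------------------------------
    key = kmscore.intersect_key_genes(km_table, feature_genes)
    if not key.genes:
        raise ValueError("key-gene set is empty; cannot subgroup")
    key_mat = methylation.gene_promoter_matrix(m, annotation, genes=key.genes)
    x = key_mat[tumor_ids].T  # samples x genes
    if k is None:
        k_star, votes = subgroup.choose_k(x, k_range=list(params.k_range))
    else:
        k_star, votes = k, pd.DataFrame()
    assignment = subgroup.cluster_samples(x, k_star)

    return MSBRResult(
        differential=diff,
        differential_genes=diff_genes,
        partition=partition,
        km_table=km_table,
        boruta=boruta,
        classifier_eval=ev,
        key_genes=key,
        assignment=assignment,
        vote_table=votes,
    )
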