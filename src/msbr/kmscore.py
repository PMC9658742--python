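"""Pathway enrichment and KMscore-based key-module selection.

A module's KMscore is the fraction of its genes that fall inside the union of
genes of all significantly enriched pathways (raw hypergeometric p < 0.05).
Modules whose score is strictly above the mean score and at least the upper
quartile are "key modules"; the key genes are the intersection of the key
modules' genes with the classifier's feature genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .comethylation import GREY, ModulePartition
from .synthetic import PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "KMScoreTable",
    "KeyGeneSet",
    "enrich_pathways",
    "compute_kmscores",
    "select_key_modules",
    "intersect_key_genes",
]


@dataclass
class EnrichmentResult:
    pathway_id: str
    overlap_count: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class KMScoreTable:
    scores: pd.Series  # index = module labels, values in [0, 1]
    module_genes: dict[str, set[str]]
    kp_genes: set[str]
    selected: list[str] = field(default_factory=list)

    @property
    def key_module_genes(self) -> set[str]:
        out: set[str] = set()
        for m in self.selected:
            out |= self.module_genes[m]
        return out


@dataclass
class KeyGeneSet:
    genes: set[str]
    provenance: pd.DataFrame  # gene, module


def enrich_pathways(
    query: set[str], pc: PathwayCollection, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of a gene set in each pathway.

    p = P(overlap >= observed) drawing |pathway| genes from the universe
    with |query| successes; no multiplicity correction (downstream
    thresholds raw p < alpha, following the module-scoring rule).
    """
    if not pc.universe:
        raise ValueError("empty gene universe")
    outside = query - pc.universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query = query & pc.universe
    n_universe = len(pc.universe)
    n_query = len(query)
    results = []
    for name in sorted(pc.pathways):
        genes = pc.pathways[name]
        overlap = len(genes & query)
        p = float(hypergeom.sf(overlap - 1, n_universe, n_query, len(genes)))
        results.append(EnrichmentResult(pathway_id=name, overlap_count=overlap, p_value=p))
    return results


def compute_kmscores(
    modules: ModulePartition,
    enr: list[EnrichmentResult],
    pc: PathwayCollection,
    cancer_related_only: bool = False,
) -> KMScoreTable:
    """KMscore_i = |KPGenes ∩ Gene_i| / |Gene_i| per non-grey module.

    KPGenes is the union of genes of all significant pathways; with
    ``cancer_related_only`` the union is restricted to pathways flagged
    cancer-related in the collection. Grey (unassigned) genes are excluded.
    """
    module_names = modules.modules
    if not module_names:
        raise ValueError("no non-grey modules to score")
    sig = [e.pathway_id for e in enr if e.significant]
    if cancer_related_only:
        sig = [p for p in sig if p in pc.cancer_related_ids]
    kp_genes: set[str] = set()
    for p in sig:
        kp_genes |= pc.pathways[p]

    module_genes = {m: set(modules.genes_of(m)) for m in module_names}
    scores = {}
    for m, genes in module_genes.items():
        if not genes:
            raise ValueError(f"module {m} has zero genes")
        scores[m] = len(kp_genes & genes) / len(genes)
    return KMScoreTable(
        scores=pd.Series(scores, name="kmscore"),
        module_genes=module_genes,
        kp_genes=kp_genes,
    )


def select_key_modules(t: KMScoreTable) -> KMScoreTable:
    """Select modules with score > mean and >= upper quartile of scores.

    The upper quartile uses the inclusive linear-interpolation convention
    (numpy's default percentile). When no module passes both tests — e.g.
    all scores equal — the top-scoring module is selected with a warning so
    downstream intersection is never empty by construction.
    """
    scores = t.scores
    if scores.empty:
        raise ValueError("no scored modules")
    mean = float(scores.mean())
    q3 = float(np.percentile(scores.to_numpy(), 75))
    selected = [m for m in scores.index if scores[m] > mean and scores[m] >= q3]
    if not selected:
        top = scores.sort_values(ascending=False, kind="stable").index[0]
        logger.warning("no module passed the mean/upper-quartile rule; "
                       "falling back to top-scoring module %r", top)
        selected = [top]
    return KMScoreTable(
        scores=t.scores, module_genes=t.module_genes, kp_genes=t.kp_genes,
        selected=sorted(selected),
    )


def intersect_key_genes(t: KMScoreTable, feature_genes: set[str]) -> KeyGeneSet:
    """Key genes = key-module genes ∩ classifier feature genes."""
    if not t.selected:
        raise ValueError("run select_key_modules first")
    if not feature_genes:
        raise ValueError("feature gene set is empty")
    rows = []
    for m in t.selected:
        for g in sorted(t.module_genes[m] & feature_genes):
            rows.append({"gene": g, "module": m})
    genes = {r["gene"] for r in rows}
    if not genes:
        logger.warning("key-module genes and feature genes are disjoint; "
                       "downstream clustering has no features")
    return KeyGeneSet(
        genes=genes,
        provenance=pd.DataFrame(rows, columns=["gene", "module"]),
    )
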