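"""Weighted co-methylation network modules (WGCNA-style).

Gene-gene adjacency is |Pearson correlation|^beta with the soft power chosen
by the scale-free topology criterion; similarity is the topological overlap
measure (TOM), and modules come from average-linkage hierarchical clustering
of 1 - TOM with a static tree cut. Modules are named by size rank with the
conventional WGCNA colors; genes in clusters below the minimum size are
labeled "grey" (unassigned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "WGCNA_COLORS",
    "adjacency_matrix",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
]

WGCNA_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

GREY = "grey"


@dataclass
class ModulePartition:
    """Gene -> module color labels; "grey" marks unassigned genes."""

    labels: pd.Series  # index = genes, values = color labels
    soft_power: int
    merge_height: float

    @property
    def module_gene_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_of(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]


def adjacency_matrix(x: pd.DataFrame, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^power over gene rows; zero diagonal."""
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(vals).max(axis=1))
    if constant.any():
        genes = list(x.index[constant])
        raise ValueError(f"constant gene rows (no correlation defined): {genes[:5]}")
    a = np.abs(np.corrcoef(vals)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) on log10(mean connectivity) over occupied bins."""
    k = connectivity[connectivity > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        return 0.0
    r = np.corrcoef(log_k, log_f)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    x: pd.DataFrame,
    powers: range | list[int] = range(1, 21),
    r2_target: float = 0.85,
) -> int:
    """Smallest power whose scale-free fit R^2 reaches the target.

    Falls back to the power maximizing R^2 when no candidate reaches it.
    """
    if x.shape[1] < 3 or x.shape[0] < 10:
        raise ValueError("need at least 10 genes and 3 samples")
    best_power, best_r2 = None, -1.0
    for p in powers:
        a = adjacency_matrix(x, p)
        r2 = _scale_free_r2(a.sum(axis=0))
        if r2 >= r2_target:
            return int(p)
        if r2 > best_r2:
            best_power, best_r2 = int(p), r2
    logger.info("no power reached R2 >= %.2f; using argmax (power=%d, R2=%.3f)",
                r2_target, best_power, best_r2)
    return best_power


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric nonnegative adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with unit diagonal. The diagonal of the input is zeroed before
    the computation.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    x: pd.DataFrame,
    soft_power: int,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Cluster genes on 1 - TOM and label modules by size rank.

    Average-linkage hierarchical clustering with a static cut at
    ``cut_height * max(merge height)``; clusters smaller than
    ``min_module_size`` become "grey".
    """
    if soft_power < 1:
        raise ValueError("soft_power must be >= 1")
    genes = list(x.index)
    if len(genes) < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size (%d): all grey",
                       len(genes), min_module_size)
        return ModulePartition(
            labels=pd.Series(GREY, index=genes), soft_power=soft_power, merge_height=0.0
        )
    a = adjacency_matrix(x, soft_power)
    tom = compute_tom(a)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0  # enforce exact symmetry for squareform
    link = average(squareform(dissim, checks=False))
    height = cut_height * link[:, 2].max()
    raw = fcluster(link, t=height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    order = big.sort_values(ascending=False).index.tolist()
    color_of = {c: WGCNA_COLORS[i % len(WGCNA_COLORS)] for i, c in enumerate(order)}
    labels = pd.Series(
        [color_of.get(c, GREY) for c in raw], index=genes, name="module"
    )
    return ModulePartition(labels=labels, soft_power=soft_power, merge_height=float(height))
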