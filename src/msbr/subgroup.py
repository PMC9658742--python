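"""Hierarchical subgrouping of samples on key-gene methylation.

Samples are clustered by Ward-linkage agglomerative clustering on the
promoter-mean beta values of the key genes. The cluster count is chosen by a
majority vote of five internal validity indices — mean silhouette,
Calinski-Harabasz, Davies-Bouldin (inverted), Dunn, and the C-index
(inverted) — over candidate k, ties broken toward smaller k. The panel mixes
compactness-oriented indices (silhouette, Davies-Bouldin) with
separation-oriented ones (Calinski-Harabasz, Dunn, C-index): the former two
tend to merge graded, nearly collinear subgroups such as ordered methylation
levels, which the latter three resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = ["SubgroupAssignment", "choose_k", "cluster_samples", "embed_2d"]


@dataclass
class SubgroupAssignment:
    labels: pd.Series  # index = sample ids, values = 0..k-1 (by size rank)
    k: int
    linkage: str
    vote_table: pd.DataFrame | None = None  # index: k candidates, cols: indices


def _cut(x: np.ndarray, k: int, method: str, metric: str) -> np.ndarray:
    link = linkage(x, method=method, metric=metric)
    return fcluster(link, t=k, criterion="maxclust")


def _dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    ks = np.unique(labels)
    intra = max(dist[np.ix_(labels == k, labels == k)].max() for k in ks)
    inter = min(
        dist[np.ix_(labels == a, labels == b)].min()
        for i, a in enumerate(ks)
        for b in ks[i + 1:]
    )
    return float(inter / intra) if intra > 0 else np.inf


def _c_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C-index: (Sw - Smin) / (Smax - Smin); smaller is better."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    within = (labels[:, None] == labels[None, :])[iu]
    d = dist[iu]
    nw = int(within.sum())
    sw = float(d[within].sum())
    d_sorted = np.sort(d)
    smin = float(d_sorted[:nw].sum())
    smax = float(d_sorted[-nw:].sum())
    return (sw - smin) / (smax - smin) if smax > smin else 0.0


def choose_k(
    x: pd.DataFrame,
    k_range=range(2, 7),
    method: str = "ward",
    metric: str = "euclidean",
) -> tuple[int, pd.DataFrame]:
    """Majority vote of five validity indices over dendrogram cuts.

    ``x`` is sample x gene. Each index votes for its best k (silhouette,
    Calinski-Harabasz and Dunn maximized; Davies-Bouldin and the C-index
    minimized, stored inverted); the k with most votes wins, ties resolved
    toward smaller k. Deterministic.
    """
    ks = list(k_range)
    vals = x.to_numpy(dtype=float)
    if vals.shape[0] <= max(ks):
        raise ValueError("need more samples than the largest candidate k")
    if np.allclose(vals, vals[0]):
        raise ValueError("all rows identical: clustering is degenerate")
    dist = squareform(pdist(vals, metric=metric))
    columns = ("silhouette", "calinski_harabasz", "davies_bouldin_inv",
               "dunn", "c_index_inv")
    rows = {}
    for k in ks:
        labels = _cut(vals, k, method, metric)
        if len(np.unique(labels)) < 2:
            rows[k] = {c: -np.inf for c in columns}
            continue
        rows[k] = {
            "silhouette": silhouette_score(vals, labels),
            "calinski_harabasz": calinski_harabasz_score(vals, labels),
            "davies_bouldin_inv": -davies_bouldin_score(vals, labels),
            "dunn": _dunn_index(dist, labels),
            "c_index_inv": -_c_index(dist, labels),
        }
    table = pd.DataFrame(rows).T
    votes: dict[int, int] = {k: 0 for k in ks}
    for col in table.columns:
        best = int(table[col].idxmax())  # idxmax returns the first (smallest) k on ties
        votes[best] += 1
    table["votes"] = pd.Series(votes, name="votes")
    return vote_winner(votes), table


def vote_winner(votes: dict[int, int]) -> int:
    """The k with most index votes; ties resolved toward smaller k."""
    max_votes = max(votes.values())
    return min(k for k, v in votes.items() if v == max_votes)


def cluster_samples(
    x: pd.DataFrame,
    k: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> SubgroupAssignment:
    """Agglomerative clustering of samples (rows of ``x``) into k subgroups.

    Output labels are 0..k-1 ordered by cluster size descending (ties by
    first occurrence), so the labeling is reproducible.
    """
    if k > x.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    raw = _cut(x.to_numpy(dtype=float), k, method, metric)
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(ascending=False, kind="stable").index.tolist()
    relabel = {c: i for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=x.index, name="subgroup")
    return SubgroupAssignment(labels=labels, k=int(len(order)), linkage=method)


def embed_2d(x: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding for visualization only; never feeds decisions."""
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to embed")
    perplexity = min(30.0, (n - 1) / 3.0)
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(x.to_numpy(dtype=float))
    return pd.DataFrame(emb, index=x.index, columns=["tsne1", "tsne2"])
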