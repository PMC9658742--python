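"""Cell-type signatures, SVR deconvolution, CYT, and methylation specificity.

The signature matrix is built from labeled single cells by one-vs-rest
Wilcoxon marker testing; bulk samples are deconvolved by nu-support-vector
regression of each standardized bulk profile on the signature columns over a
small nu grid, keeping the best-fitting solution and projecting coefficients
onto the simplex. Immune readouts: the cytolytic activity score CYT (mean of
GZMA and PRF1 expression) and an entropy-based subgroup-specificity score
for per-gene methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.svm import NuSVR
from statsmodels.stats.multitest import multipletests

from .synthetic import LabeledCellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "ProportionMatrix",
    "ImmuneScores",
    "build_signature",
    "deconvolve",
    "compute_cyt",
    "methylation_specificity",
]


@dataclass
class SignatureMatrix:
    values: pd.DataFrame  # marker gene x cell type, nonnegative
    marker_genes_per_type: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature must be nonnegative")
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("signature has all-zero rows")


@dataclass
class ProportionMatrix:
    values: pd.DataFrame  # sample x cell type, rows on the simplex
    fit_quality: pd.DataFrame  # per sample: rmse, pearson_r, nu

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < -1e-12).any():
            raise ValueError("proportions must be nonnegative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")


@dataclass
class ImmuneScores:
    cyt: pd.Series | None = None
    specificity: pd.Series | None = None  # per-gene entropy (bits)
    specific_gene_flags: pd.Series | None = None


def build_signature(
    cells: LabeledCellMatrix, min_lfc: float = 1.0, max_p: float = 0.05
) -> SignatureMatrix:
    """Marker-based signature from labeled single cells.

    Per cell type, a one-vs-rest Wilcoxon rank-sum test on log1p expression
    with Benjamini-Hochberg correction; markers need FDR < ``max_p`` and
    log-fold-change (difference of log1p means) >= ``min_lfc``. The signature
    column is the per-type sum of raw expression restricted to the union of
    all marker genes.
    """
    expr = cells.expression
    types = sorted(cells.cell_types.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    logx = np.log1p(expr.to_numpy(dtype=float))
    markers: dict[str, list[str]] = {}
    for ct in types:
        in_type = (cells.cell_types == ct).to_numpy()
        if in_type.sum() < 2:
            raise ValueError(f"cell type {ct} has fewer than 2 cells")
        a, b = logx[:, in_type], logx[:, ~in_type]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(invalid="ignore"):
            p = mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
        p = np.where(np.isnan(p), 1.0, p)
        fdr = multipletests(p, method="fdr_bh")[1]
        hit = (fdr < max_p) & (lfc >= min_lfc)
        markers[ct] = list(expr.index[hit])
        if not markers[ct]:
            raise ValueError(f"cell type {ct} has no marker genes")
    union = sorted(set().union(*markers.values()))
    cols = {}
    for ct in types:
        in_type = (cells.cell_types == ct).to_numpy()
        cols[ct] = expr.loc[union].to_numpy()[:, in_type].sum(axis=1)
    sig = pd.DataFrame(cols, index=union)
    return SignatureMatrix(values=sig, marker_genes_per_type=markers)


def _deconvolve_sample(y: np.ndarray, X: np.ndarray, nu_grid) -> tuple[np.ndarray, float, float, float]:
    """nu-SVR fit of one standardized bulk profile on signature columns."""
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=10.0)
        model.fit(X, y)
        w = model.coef_.ravel()
        pred = model.predict(X)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if best is None or rmse < best[2]:
            r = float(np.corrcoef(pred, y)[0, 1]) if np.std(pred) > 0 else 0.0
            best = (w, nu, rmse, r)
    w, nu, rmse, r = best
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total == 0:
        w = np.full_like(w, 1.0 / w.size)
    else:
        w = w / total
    return w, nu, rmse, r


def deconvolve(
    bulk: pd.DataFrame,
    sig: SignatureMatrix,
    nu_grid=(0.25, 0.5, 0.75),
) -> ProportionMatrix:
    """Estimate cell-type proportions per bulk sample by linear nu-SVR.

    Genes are intersected by name; the signature matrix is standardized by
    its global mean and standard deviation (a single affine map, so relative
    column scales — and hence proportions — are preserved) and each bulk
    profile is standardized per sample. For each sample the nu with the
    lowest reconstruction RMSE wins; negative coefficients are clipped to
    zero and the rest renormalized onto the simplex.
    """
    common = [g for g in sig.values.index if g in set(bulk.index)]
    if not common:
        raise ValueError("no genes shared between bulk and signature")
    if len(common) < sig.values.shape[1]:
        raise ValueError("need at least as many shared genes as cell types")
    S = sig.values.loc[common].to_numpy(dtype=float)
    X = (S - S.mean()) / S.std()
    B = bulk.loc[common].to_numpy(dtype=float)

    rows, quality = [], []
    for j, sample in enumerate(bulk.columns):
        y = B[:, j]
        y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        w, nu, rmse, r = _deconvolve_sample(y, X, nu_grid)
        rows.append(w)
        quality.append({"sample": sample, "rmse": rmse, "pearson_r": r, "nu": nu})
    props = pd.DataFrame(rows, index=bulk.columns, columns=list(sig.values.columns))
    return ProportionMatrix(
        values=props, fit_quality=pd.DataFrame(quality).set_index("sample")
    )


def compute_cyt(bulk: pd.DataFrame, gzma: str = "GZMA", prf1: str = "PRF1") -> pd.Series:
    """Cytolytic activity: per-sample mean of GZMA and PRF1 expression."""
    for g in (gzma, prf1):
        if g not in bulk.index:
            raise ValueError(f"gene {g} not present in the expression matrix")
    return ((bulk.loc[gzma] + bulk.loc[prf1]) / 2.0).rename("CYT")


def methylation_specificity(
    subgroup_means: pd.DataFrame,
    kw_p: pd.Series,
    entropy_quantile: float = 0.25,
    max_p: float = 0.05,
) -> ImmuneScores:
    """Entropy-based subgroup specificity of per-gene methylation.

    ``subgroup_means`` is gene x subgroup mean beta in [0,1]. Means are
    normalized per gene to a distribution over subgroups; low Shannon
    entropy marks genes whose methylation concentrates in few subgroups.
    A gene is flagged specific iff its entropy falls below the
    ``entropy_quantile`` of all candidate genes AND its Kruskal-Wallis
    p-value is below ``max_p``. All-zero genes get the maximal entropy
    log2(k) (uninformative) and are never flagged.
    """
    m = subgroup_means.to_numpy(dtype=float)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 subgroups")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("means must lie in [0, 1]")
    k = m.shape[1]
    totals = m.sum(axis=1)
    ent = np.full(m.shape[0], np.log2(k))
    ok = totals > 0
    p = m[ok] / totals[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    ent[ok] = terms.sum(axis=1)
    entropy = pd.Series(ent, index=subgroup_means.index, name="entropy")
    cutoff = float(np.quantile(entropy.to_numpy(), entropy_quantile))
    flags = (entropy < cutoff) & (kw_p.reindex(entropy.index) < max_p) & ok
    return ImmuneScores(specificity=entropy, specific_gene_flags=flags.rename("specific"))
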