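"""Promoter mapping, probe QC, KNN imputation, and differential methylation.

The differential unit is the HM450K-style CpG probe carrying a beta value in
[0,1]. Promoter probes are those within 2000 bp upstream to 500 bp downstream
of a gene's transcription start, oriented by strand. Probes with too many
missing beta values are dropped; the rest are completed by k-nearest-neighbor
imputation over probe rows. Differential sites are called by a per-probe
Student's t-test with Benjamini-Hochberg FDR, flagged when |beta_d| >= 0.2
and FDR < 0.05, then mapped to genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "promoter_probes",
    "filter_missingness",
    "knn_impute",
    "call_differential",
    "sites_to_genes",
    "gene_promoter_matrix",
]


@dataclass
class BetaMatrix:
    """Probe x sample beta values with explicit missingness (NaN).

    ``sample_groups`` maps each sample to a group label such as "tumor" or
    "normal"; downstream code also stores subgroup labels here.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        observed = v[~np.isnan(v)]
        if observed.size and (observed.min() < 0.0 or observed.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("probe and sample ids must be unique")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, probes) -> "BetaMatrix":
        keep = [p for p in self.probe_ids if p in set(probes)]
        return BetaMatrix(self.values.loc[keep], dict(self.sample_groups))

    @classmethod
    def read_tsv(cls, path, groups_path=None) -> "BetaMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        groups = {}
        if groups_path is not None:
            g = pd.read_csv(groups_path, sep="\t", index_col=0)
            groups = g.iloc[:, 0].to_dict()
        return cls(values, groups)


@dataclass
class ProbeAnnotation:
    """One row per probe: probe_id, chrom, pos (0-based), strand, gene_symbol, tss."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "pos", "strand", "gene_symbol", "tss")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("annotation must have one row per probe")
        if (self.table["pos"] < 0).any():
            raise ValueError("positions must be nonnegative")

    def gene_of_probe(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"]

    @classmethod
    def read_tsv(cls, path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


def promoter_probes(
    ann: ProbeAnnotation, upstream: int = 2000, downstream: int = 500
) -> set[str]:
    """Probes whose position falls in the strand-oriented promoter window.

    For a + strand gene the window is the half-open interval
    [tss - upstream, tss + downstream); for a - strand gene it is reflected
    through the TSS: (tss - downstream, tss + upstream], i.e. the half-open
    interval [tss - downstream + 1, tss + upstream + 1). The TSS itself is
    included on both strands.
    """
    t = ann.table
    bad = ~t["strand"].isin(["+", "-"])
    if bad.any():
        probes = t.loc[bad, "probe_id"].tolist()
        raise ValueError(f"unknown strand for probes: {probes[:5]}")
    pos, tss = t["pos"].to_numpy(), t["tss"].to_numpy()
    plus = t["strand"].to_numpy() == "+"
    in_plus = (pos >= tss - upstream) & (pos < tss + downstream)
    in_minus = (pos > tss - downstream) & (pos <= tss + upstream)
    keep = np.where(plus, in_plus, in_minus)
    return set(t.loc[keep, "probe_id"])


def filter_missingness(m: BetaMatrix, max_missing: float = 0.5) -> BetaMatrix:
    """Drop probes whose missing fraction strictly exceeds ``max_missing``."""
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("missingness filter dropped every probe")
    if n_dropped:
        logger.info("filter_missingness: dropped %d/%d probes", n_dropped, len(frac))
    return BetaMatrix(m.values.loc[keep], dict(m.sample_groups))


def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Replace each missing entry by the mean of the k nearest probes.

    Probe-probe distance is Euclidean over commonly observed samples
    (scaled to the full dimension); for each missing entry the k nearest
    probes observed in that sample contribute, ties broken by probe order.
    Already-complete matrices pass through unchanged.
    """
    values = m.values.to_numpy(dtype=float)
    n_probes = values.shape[0]
    if k >= n_probes:
        raise ValueError(f"k={k} must be smaller than the number of probes ({n_probes})")
    if (np.isnan(values).all(axis=1)).any():
        raise ValueError("every probe needs at least one observed value")
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return m
    dist = nan_euclidean_distances(values)
    np.fill_diagonal(dist, np.inf)
    out = values.copy()
    for j in range(values.shape[1]):
        missing_rows = np.flatnonzero(nan_mask[:, j])
        if missing_rows.size == 0:
            continue
        observed_rows = np.flatnonzero(~nan_mask[:, j])
        for i in missing_rows:
            d = dist[i, observed_rows]
            d = np.where(np.isnan(d), np.inf, d)
            order = np.argsort(d, kind="stable")[:k]
            out[i, j] = values[observed_rows[order], j].mean()
    assert not np.isnan(out).any()
    return BetaMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        dict(m.sample_groups),
    )


def call_differential(
    m: BetaMatrix,
    case_ids,
    control_ids,
    min_abs_bd: float = 0.2,
    max_fdr: float = 0.05,
    welch: bool = False,
    annotation: ProbeAnnotation | None = None,
) -> pd.DataFrame:
    """Per-probe differential methylation between case and control samples.

    Returns a DataFrame with probe_id, gene_symbol (if annotation given),
    mean_case, mean_control, beta_d, p_value, fdr, is_differential. The test
    is a two-sided pooled-variance Student's t-test (Welch behind a flag);
    FDR is Benjamini-Hochberg over all tested probes; a probe is flagged
    differential iff |beta_d| >= min_abs_bd and fdr < max_fdr. Probes with
    zero variance in both groups get p = 1.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control sample sets overlap")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    case = m.values[case_ids].to_numpy(dtype=float)
    control = m.values[control_ids].to_numpy(dtype=float)
    if np.isnan(case).any() or np.isnan(control).any():
        raise ValueError("matrix contains missing values; impute first")

    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    beta_d = mean_case - mean_control
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=not welch)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    fdr = multipletests(p, method="fdr_bh")[1]
    flagged = (np.abs(beta_d) >= min_abs_bd) & (fdr < max_fdr)

    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "beta_d": beta_d,
            "p_value": p,
            "fdr": fdr,
            "is_differential": flagged,
        }
    )
    if annotation is not None:
        out = out.merge(
            annotation.table[["probe_id", "gene_symbol"]], on="probe_id", how="left"
        )
    return out


def sites_to_genes(dt: pd.DataFrame, annotation: ProbeAnnotation | None = None) -> set[str]:
    """Unique gene symbols carrying at least one flagged differential probe."""
    t = dt
    if "gene_symbol" not in t.columns:
        if annotation is None:
            raise ValueError("need gene_symbol column or an annotation")
        t = t.merge(annotation.table[["probe_id", "gene_symbol"]], on="probe_id", how="left")
    flagged = t.loc[t["is_differential"], "gene_symbol"].dropna()
    return set(flagged)


def gene_promoter_matrix(
    m: BetaMatrix,
    annotation: ProbeAnnotation,
    genes=None,
    upstream: int = 2000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Gene x sample matrix of promoter-mean beta values.

    Averages each gene's promoter probes (per the strand-oriented window)
    that are present in the matrix. Restricted to ``genes`` when given.
    """
    promoters = promoter_probes(annotation, upstream, downstream)
    gene_of = annotation.gene_of_probe()
    present = [p for p in m.probe_ids if p in promoters]
    if genes is not None:
        wanted = set(genes)
        present = [p for p in present if gene_of[p] in wanted]
    if not present:
        raise ValueError("no promoter probes for the requested genes")
    sub = m.values.loc[present]
    return sub.groupby(gene_of.loc[present]).mean()
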