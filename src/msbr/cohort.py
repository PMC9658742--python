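"""Subgroup comparisons: survival, clinical stage, and feature tests.

Survival uses the Kaplan-Meier product-limit estimator and the log-rank
test (any number of groups). Categorical stage and TILs tables are compared
by Pearson chi-square without continuity correction; numeric per-sample
features by the Kruskal-Wallis rank test. A summary builder collects
per-subgroup descriptive tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "km_curve",
    "logrank",
    "chi_square",
    "kruskal_wallis",
    "summarize_subgroups",
]


def _aligned_groups(t: pd.DataFrame, group: pd.Series) -> pd.Series:
    g = group.reindex(t["sample_id"])
    if g.isna().any():
        missing = list(t.loc[g.isna().to_numpy(), "sample_id"])
        raise ValueError(f"samples without subgroup labels: {missing[:5]}")
    return g


def km_curve(t: pd.DataFrame, group: pd.Series) -> dict:
    """Kaplan-Meier survival step function per subgroup.

    ``t`` needs sample_id, time, event columns; ``group`` maps sample ids to
    subgroup labels. Returns {label: DataFrame(time, survival)} where the
    survival column starts at 1 and is non-increasing.
    """
    g = _aligned_groups(t, group)
    curves = {}
    for label in sorted(g.unique()):
        mask = (g == label).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty subgroup {label}")
        kmf = KaplanMeierFitter()
        kmf.fit(t.loc[mask, "time"], event_observed=t.loc[mask, "event"])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def logrank(t: pd.DataFrame, group: pd.Series) -> tuple[float, float]:
    """Log-rank test across 2+ subgroups; chi-square with (g-1) df."""
    g = _aligned_groups(t, group)
    if g.nunique() < 2:
        raise ValueError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(
        t["time"].to_numpy(), g.to_numpy(), t["event"].to_numpy()
    )
    return float(res.test_statistic), float(res.p_value)


def chi_square(contingency: pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-square on an r x c count table, no continuity correction.

    All-zero rows/columns are dropped with a warning (they contribute no
    information and break the expected-count formula).
    """
    table = contingency.to_numpy(dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping %d zero rows and %d zero columns",
                       int((~keep_r).sum()), int((~keep_c).sum()))
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zeros")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def kruskal_wallis(values: pd.Series, group: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction across 2+ subgroups."""
    g = group.reindex(values.index)
    samples = [values[g == label].to_numpy() for label in sorted(g.dropna().unique())]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def summarize_subgroups(
    assignment: pd.Series,
    clinical: pd.DataFrame | None = None,
    cyt: pd.Series | None = None,
    proportions: pd.DataFrame | None = None,
    tils: pd.Series | None = None,
    expression: pd.DataFrame | None = None,
    checkpoint_genes: tuple[str, str] = ("PDCD1", "CD274"),
) -> dict:
    """Per-subgroup descriptive report assembled from available artifacts.

    Checks id consistency (artifact samples must be labeled), then reports
    per subgroup: size, stage proportions, median CYT, mean cell-type
    proportions, TILs-type proportions, and median checkpoint-gene
    expression. Returns a JSON-serializable dict of tables.
    """
    labeled = set(assignment.index)
    report: dict = {"subgroup_sizes": assignment.value_counts().sort_index().to_dict()}
    if 0 in pd.Series(report["subgroup_sizes"]).to_numpy():
        raise ValueError("empty subgroup in assignment")

    def check_ids(ids, what):
        orphans = sorted(set(ids) - labeled)
        if orphans:
            raise ValueError(f"{what} samples without subgroup labels: {orphans[:5]}")

    if clinical is not None:
        check_ids(clinical["sample_id"], "clinical")
        stages = {}
        cl = clinical.set_index("sample_id")
        for col in ("stage_T", "stage_N", "stage_M"):
            if col not in cl.columns:
                continue
            tab = pd.crosstab(assignment, cl[col].reindex(assignment.index))
            stages[col] = tab.div(tab.sum(axis=1), axis=0).round(6).to_dict()
        report["stage_proportions"] = stages
    if cyt is not None:
        check_ids(cyt.index, "CYT")
        report["median_cyt"] = cyt.groupby(assignment.reindex(cyt.index)).median().to_dict()
    if proportions is not None:
        check_ids(proportions.index, "proportion")
        report["mean_cell_proportions"] = (
            proportions.groupby(assignment.reindex(proportions.index)).mean().round(6)
            .to_dict(orient="index")
        )
    if tils is not None:
        check_ids(tils.dropna().index, "TILs")
        tab = pd.crosstab(assignment, tils.reindex(assignment.index))
        report["tils_proportions"] = tab.div(tab.sum(axis=1), axis=0).round(6).to_dict()
    if expression is not None:
        check_ids(expression.columns, "expression")
        med = {}
        for gene in checkpoint_genes:
            if gene in expression.index:
                med[gene] = (
                    expression.loc[gene].groupby(assignment.reindex(expression.columns))
                    .median().to_dict()
                )
        report["median_checkpoint_expression"] = med
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
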