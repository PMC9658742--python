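"""Compare the detected subgroups on survival, stage, CYT, and infiltration.

Kaplan-Meier curves and the log-rank test across subgroups, chi-square on
the clinical T/N/M stage tables, Kruskal-Wallis on CYT and per-cell-type
proportions, and the per-subgroup summary report.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msbr.cohort import (  # noqa: E402
    chi_square,
    km_curve,
    kruskal_wallis,
    logrank,
    summarize_subgroups,
    write_report,
)

DATA = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"
OUT = Path(__file__).resolve().parents[1] / "results"


def run(name):
    d, outdir = DATA / name, OUT / name
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t")
    bulk = pd.read_csv(d / "bulk_expression.tsv", sep="\t", index_col=0)
    subgroups = pd.read_csv(outdir / "subgroups.tsv", sep="\t", index_col=0)["subgroup"]
    cyt = pd.read_csv(outdir / "cyt.tsv", sep="\t", index_col=0).iloc[:, 0]
    props = pd.read_csv(outdir / "cell_proportions.tsv", sep="\t", index_col=0)

    chi2, p_surv = logrank(clinical, subgroups)
    curves = km_curve(clinical, subgroups)
    km_long = pd.concat(
        {label: c.set_index("time")["survival"] for label, c in curves.items()},
        names=["subgroup", "time"],
    )
    km_long.rename("survival").to_csv(outdir / "km_curves.tsv", sep="\t")

    stage_tests = {}
    for col in ("stage_T", "stage_N", "stage_M"):
        table = pd.crosstab(
            subgroups.loc[clinical["sample_id"]].to_numpy(),
            clinical[col].to_numpy(),
        )
        stage_tests[col] = chi_square(table)[1]

    _, p_cyt = kruskal_wallis(cyt, subgroups)
    prop_tests = {
        ct: kruskal_wallis(props[ct], subgroups)[1] for ct in props.columns
    }

    report = summarize_subgroups(
        subgroups, clinical=clinical, cyt=cyt, proportions=props, expression=bulk
    )
    report["tests"] = {
        "logrank_p": p_surv,
        "stage_chi_square_p": stage_tests,
        "cyt_kruskal_p": p_cyt,
        "proportion_kruskal_p": prop_tests,
    }
    write_report(report, outdir / "subgroup_report.json")
    print(f"{name}: log-rank p={p_surv:.2e}; CYT Kruskal-Wallis p={p_cyt:.2e}; "
          f"stage-T chi-square p={stage_tests['stage_T']:.3f}")
    sizes = report["subgroup_sizes"]
    med = report["median_cyt"]
    for s in sorted(sizes):
        print(f"  subgroup {s}: n={sizes[s]}, median CYT={med[s]:.2f}")


if __name__ == "__main__":
    run("luminal_a")
    run("luminal_b")
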