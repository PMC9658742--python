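"""Call differential promoter methylation, tumor vs. normal, per cohort.

Reads the cohorts written by 01_simulate_cohorts.py, restricts probes to
strand-oriented promoter windows, applies the missingness filter and KNN
imputation, runs the per-probe t-test with BH correction, and writes the
differential table plus the derived gene set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msbr import methylation  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"
OUT = Path(__file__).resolve().parents[1] / "results"


def call(name):
    d = DATA / name
    beta = methylation.BetaMatrix.read_tsv(d / "beta.tsv", d / "sample_groups.tsv")
    ann = methylation.ProbeAnnotation.read_tsv(d / "annotation.tsv")
    tumors = [s for s, g in beta.sample_groups.items() if g == "tumor"]
    normals = [s for s, g in beta.sample_groups.items() if g == "normal"]

    m = beta.subset_probes(methylation.promoter_probes(ann))
    m = methylation.filter_missingness(m)
    m = methylation.knn_impute(m)
    table = methylation.call_differential(m, tumors, normals, annotation=ann)
    genes = methylation.sites_to_genes(table)

    outdir = OUT / name
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "differential_sites.tsv", sep="\t", index=False)
    (outdir / "differential_genes.txt").write_text("\n".join(sorted(genes)) + "\n")
    n_sites = int(table["is_differential"].sum())
    print(f"{name}: {n_sites}/{len(table)} differential sites -> "
          f"{len(genes)} differential genes")


if __name__ == "__main__":
    call("luminal_a")
    call("luminal_b")
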