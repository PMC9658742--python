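"""Generate the two synthetic luminal-like cohorts and write them to disk.

Produces, for each preset (two planted subgroups mirroring a luminal-A-like
cohort; three mirroring luminal B): the probe x sample beta matrix with
missingness, the probe annotation, pathway gene sets, bulk expression,
labeled single cells, a clinical table, and the ground-truth JSON.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from msbr.synthetic import (  # noqa: E402
    generate_bulk_expression,
    generate_cohort,
    generate_pathways,
    generate_single_cell,
    generate_survival,
    luminal_a_preset,
    luminal_b_preset,
    write_cohort,
)

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohorts"


def simulate(name, preset, seed):
    outdir = OUT / name
    beta, ann, truth = generate_cohort(preset(seed=seed))
    write_cohort(outdir, beta, ann, truth)
    pathways = generate_pathways(truth, universe=set(ann.table["gene_symbol"]),
                                 seed=seed)
    pathways.write_gmt(outdir / "pathways.gmt")
    bulk = generate_bulk_expression(truth, noise_sd=0.1, seed=seed)
    bulk.to_csv(outdir / "bulk_expression.tsv", sep="\t")
    cells = generate_single_cell(truth, cells_per_type=40, dispersion=0.3, seed=seed)
    cells.expression.to_csv(outdir / "single_cells.tsv", sep="\t")
    cells.cell_types.rename("cell_type").rename_axis("cell_id").to_csv(
        outdir / "cell_labels.tsv", sep="\t"
    )
    clinical = generate_survival(
        truth, hazard_by_subgroup={s: (3 - 2 * s / max(1, len(set(truth.subgroup_of_sample.values())) - 1)) / 365
                                   for s in set(truth.subgroup_of_sample.values())},
        censor_rate=0.25, seed=seed,
    )
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    n_missing = int(beta.values.isna().to_numpy().sum())
    print(f"{name}: {beta.values.shape[0]} probes x {beta.values.shape[1]} samples, "
          f"{n_missing} missing entries, k={len(set(truth.subgroup_of_sample.values()))} "
          f"planted subgroups -> {outdir}")


if __name__ == "__main__":
    simulate("luminal_a", luminal_a_preset, SEED)
    simulate("luminal_b", luminal_b_preset, SEED + 101)
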