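"""Generators: cohorts, pathways, single cells, bulk expression, survival."""

import numpy as np
import pandas as pd
import pytest

from msbr.kmscore import enrich_pathways
from msbr.synthetic import (
    CohortSpec,
    GroundTruth,
    PathwayCollection,
    generate_bulk_expression,
    generate_cohort,
    generate_comethylation_blocks,
    generate_pathways,
    generate_single_cell,
    generate_survival,
    luminal_a_preset,
    luminal_b_preset,
    write_cohort,
)

from conftest import group_ids


class TestCohortSpec:
    def test_props_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subgroups=2, subgroup_props=(0.6, 0.6))

    def test_missingness_that_would_empty_the_fixture_is_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(missing_rate=0.6)

    def test_default_props_uniform(self):
        spec = CohortSpec(n_subgroups=3, n_tumor=48)
        assert spec.subgroup_props == (1 / 3, 1 / 3, 1 / 3)


class TestGenerateCohort:
    def test_values_in_unit_interval_with_missingness(self, cohort_a):
        beta, _, _ = cohort_a
        v = beta.values.to_numpy()
        obs = v[~np.isnan(v)]
        assert obs.min() >= 0.0 and obs.max() <= 1.0

    def test_detectable_key_probes_in_expectation(self):
        """At near-zero noise every key-gene probe separates pooled tumors
        from normals by at least the 0.2 calling threshold."""
        beta, ann, truth = generate_cohort(
            luminal_a_preset(seed=1, missing_rate=0.0, beta_noise=5e5)
        )
        tumors, normals = group_ids(beta, "tumor"), group_ids(beta, "normal")
        gene_of = ann.gene_of_probe()
        key_probes = gene_of.index[gene_of.isin(truth.key_gene_ids)]
        shift = (
            beta.values.loc[key_probes, tumors].mean(axis=1)
            - beta.values.loc[key_probes, normals].mean(axis=1)
        )
        assert (shift.abs() >= 0.2).all()

    def test_bitwise_reproducible_from_seed(self):
        spec = luminal_a_preset(seed=7)
        b1, a1, t1 = generate_cohort(spec)
        b2, a2, t2 = generate_cohort(spec)
        assert b1.values.equals(b2.values)
        assert a1.table.equals(a2.table)
        assert t1.subgroup_of_sample == t2.subgroup_of_sample
        assert t1.true_proportions.equals(t2.true_proportions)

    def test_observed_missing_fraction_near_target(self):
        spec = CohortSpec(n_probes=500, missing_rate=0.1, seed=3)
        beta, _, _ = generate_cohort(spec)
        frac = beta.values.isna().to_numpy().mean()
        assert abs(frac - 0.1) <= 0.02  # binomial sd over 500*60 entries ~ 0.002

    def test_every_key_gene_has_promoter_probes(self, cohort_a):
        from msbr.methylation import promoter_probes

        _, ann, truth = cohort_a
        promoters = promoter_probes(ann)
        gene_of = ann.gene_of_probe()
        promoted = set(gene_of.loc[list(promoters)])
        assert set(truth.key_gene_ids) <= promoted

    def test_ground_truth_round_trips_through_json(self, cohort_a, tmp_path):
        _, _, truth = cohort_a
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.subgroup_of_sample == truth.subgroup_of_sample
        assert back.key_gene_ids == truth.key_gene_ids
        assert back.planted_module_of_gene == truth.planted_module_of_gene
        pd.testing.assert_frame_equal(
            back.true_proportions.loc[truth.true_proportions.index,
                                      truth.true_proportions.columns],
            truth.true_proportions,
        )

    def test_cohort_files_round_trip(self, cohort_a, tmp_path):
        from msbr.methylation import BetaMatrix, ProbeAnnotation

        beta, ann, truth = cohort_a
        write_cohort(tmp_path, beta, ann, truth)
        b2 = BetaMatrix.read_tsv(tmp_path / "beta.tsv", tmp_path / "sample_groups.tsv")
        a2 = ProbeAnnotation.read_tsv(tmp_path / "annotation.tsv")
        assert np.allclose(
            b2.values.to_numpy(), beta.values.to_numpy(), equal_nan=True
        )
        assert b2.sample_groups == beta.sample_groups
        assert a2.table["probe_id"].tolist() == ann.table["probe_id"].tolist()


class TestGeneratePathways:
    def test_full_overlap_pathway_is_most_enriched(self, cohort_a):
        _, ann, truth = cohort_a
        universe = set(ann.table["gene_symbol"])
        pc = generate_pathways(truth, n_pathways=6, overlap=1.0, universe=universe, seed=0)
        module0 = {g for g, m in truth.planted_module_of_gene.items() if m == 0}
        res = enrich_pathways(module0, pc)
        best = min(res, key=lambda r: r.p_value)
        assert best.pathway_id in pc.cancer_related_ids

    def test_zero_overlap_gives_background_rate(self, cohort_a):
        _, ann, truth = cohort_a
        universe = set(ann.table["gene_symbol"])
        planted = set(truth.planted_module_of_gene)
        hits = total = 0
        for seed in range(40):
            pc = generate_pathways(
                truth, n_pathways=5, overlap=0.0, universe=universe, seed=seed
            )
            for genes in pc.pathways.values():
                hits += len(genes & planted)
                total += len(genes)
        background = len(planted) / len(universe)
        assert hits / total == pytest.approx(background, abs=0.05)

    def test_zero_pathways_is_valid_empty_gmt(self, cohort_a, tmp_path):
        _, ann, truth = cohort_a
        pc = generate_pathways(truth, n_pathways=0, universe=set(ann.table["gene_symbol"]))
        assert pc.pathways == {}
        path = tmp_path / "empty.gmt"
        pc.write_gmt(path)
        assert PathwayCollection.read_gmt(path).pathways == {}

    def test_gmt_round_trip(self, pathways_a, tmp_path):
        path = tmp_path / "pw.gmt"
        pathways_a.write_gmt(path)
        back = PathwayCollection.read_gmt(path, universe=pathways_a.universe)
        assert back.pathways == pathways_a.pathways
        assert back.cancer_related_ids == pathways_a.cancer_related_ids

    def test_excessive_overlap_is_error(self, cohort_a):
        _, ann, truth = cohort_a
        with pytest.raises(ValueError):
            generate_pathways(
                truth, overlap=1.0, pathway_size=60,
                universe=set(ann.table["gene_symbol"]),
            )


class TestGenerateSingleCell:
    def test_cell_count_and_labels(self, cohort_a):
        _, _, truth = cohort_a
        cells = generate_single_cell(truth, cells_per_type=50, seed=0)
        n_types = truth.true_signature.shape[1]
        assert cells.expression.shape[1] == 50 * n_types
        assert cells.cell_types.value_counts().eq(50).all()

    def test_zero_dispersion_recovers_signature_columns(self, cohort_a):
        _, _, truth = cohort_a
        cells = generate_single_cell(truth, cells_per_type=10, dispersion=0.0, seed=0)
        for ct in truth.true_signature.columns:
            members = cells.cell_types.index[cells.cell_types == ct]
            mean = cells.expression[members].mean(axis=1)
            assert np.allclose(mean, truth.true_signature[ct])

    def test_reproducible(self, cohort_a):
        _, _, truth = cohort_a
        c1 = generate_single_cell(truth, seed=5)
        c2 = generate_single_cell(truth, seed=5)
        assert c1.expression.equals(c2.expression)


class TestGenerateBulk:
    def test_zero_noise_is_exact_mixture(self, cohort_a):
        _, _, truth = cohort_a
        bulk = generate_bulk_expression(truth, noise_sd=0.0, seed=0)
        expected = truth.true_signature.to_numpy() @ truth.true_proportions.to_numpy().T
        assert np.allclose(bulk.to_numpy(), expected)

    def test_nonnegative(self, cohort_a):
        _, _, truth = cohort_a
        bulk = generate_bulk_expression(truth, noise_sd=0.5, seed=1)
        assert (bulk.to_numpy() >= 0).all()

    def test_residual_sd_near_target(self, cohort_a):
        _, _, truth = cohort_a
        clean = truth.true_signature.to_numpy() @ truth.true_proportions.to_numpy().T
        bulk = generate_bulk_expression(truth, noise_sd=0.1, seed=2)
        resid = bulk.to_numpy() - clean
        # clipping at zero barely bites: signature entries are well above 0
        assert abs(resid[clean > 1].std() - 0.1) <= 0.02


class TestGenerateSurvival:
    def test_zero_censoring_observes_all_events(self, cohort_a):
        _, _, truth = cohort_a
        cl = generate_survival(truth, censor_rate=0.0, seed=0)
        assert (cl["event"] == 1).all()

    def test_censor_rate_matches_target_in_expectation(self, cohort_a):
        _, _, truth = cohort_a
        fracs = [
            1 - generate_survival(truth, censor_rate=0.3, seed=s)["event"].mean()
            for s in range(25)
        ]
        assert abs(np.mean(fracs) - 0.3) <= 0.05

    def test_stage_columns_are_categorical(self, cohort_a):
        _, _, truth = cohort_a
        cl = generate_survival(truth, seed=1)
        assert set(cl["stage_T"]) <= {"T1", "T2", "T3", "T4"}
        assert set(cl["stage_N"]) <= {"N0", "N1", "N2"}
        assert set(cl["stage_M"]) <= {"M0", "M1"}

    def test_nonpositive_hazard_is_error(self, cohort_a):
        _, _, truth = cohort_a
        with pytest.raises(ValueError):
            generate_survival(truth, hazard_by_subgroup={0: 0.0, 1: 1.0})

    def test_hazard_ratio_three_is_detected(self, cohort_a):
        """Planted hazard ratio 3 between subgroups yields a significant
        log-rank difference in most replicates."""
        from msbr.cohort import logrank

        _, _, truth = cohort_a
        hits = 0
        for s in range(10):
            cl = generate_survival(
                truth, hazard_by_subgroup={0: 3 / 365, 1: 1 / 365},
                censor_rate=0.2, seed=s,
            )
            g = pd.Series(truth.subgroup_of_sample)
            _, p = logrank(cl, g)
            hits += p < 0.05
        assert hits >= 8


class TestBlocks:
    def test_block_correlation_near_target(self):
        x, labels = generate_comethylation_blocks(
            n_blocks=2, genes_per_block=30, n_samples=200, intra_cor=0.8, seed=0
        )
        corr = np.corrcoef(x.to_numpy())
        same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert corr[same & off].mean() == pytest.approx(0.8, abs=0.07)
        assert abs(corr[~same].mean()) <= 0.05
        assert x.to_numpy().min() >= 0.0 and x.to_numpy().max() <= 1.0
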