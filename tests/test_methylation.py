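"""Promoter windows, missingness QC, KNN imputation, differential calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from msbr.methylation import (
    BetaMatrix,
    ProbeAnnotation,
    call_differential,
    filter_missingness,
    gene_promoter_matrix,
    knn_impute,
    promoter_probes,
    sites_to_genes,
)
from msbr.synthetic import generate_cohort, luminal_a_preset

from conftest import group_ids


def _ann(rows):
    return ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "strand", "gene_symbol", "tss"])
    )


class TestPromoterProbes:
    @pytest.mark.parametrize(
        "strand,pos,expected",
        [
            ("+", 8000, True),    # 2000 bp upstream boundary, inclusive
            ("+", 7999, False),
            ("+", 10499, True),   # just inside downstream edge
            ("+", 10500, False),  # 500 bp downstream, half-open
            ("+", 10000, True),   # the TSS itself
            ("-", 11999, True),   # 1999 bp upstream on the - strand
            ("-", 12000, True),   # 2000 bp upstream boundary
            ("-", 12001, False),
            ("-", 9501, True),    # just inside the downstream edge
            ("-", 9500, False),
            ("-", 10000, True),   # the TSS itself
        ],
    )
    def test_window_boundaries(self, strand, pos, expected):
        ann = _ann([("p1", "chr1", pos, strand, "G1", 10000)])
        assert (("p1" in promoter_probes(ann)) is expected)

    def test_unknown_strand_names_probe(self):
        ann = _ann([("pX", "chr1", 5, ".", "G1", 10)])
        with pytest.raises(ValueError, match="pX"):
            promoter_probes(ann)


class TestFilterMissingness:
    def test_exceeding_is_strict(self):
        vals = pd.DataFrame(
            np.full((2, 10), 0.5), index=["p6", "p5"], columns=[f"s{i}" for i in range(10)]
        )
        vals.iloc[0, :6] = np.nan  # 6/10 missing: dropped
        vals.iloc[1, :5] = np.nan  # 5/10 missing: kept (strictly greater only)
        out = filter_missingness(BetaMatrix(vals))
        assert out.probe_ids == ["p5"]

    def test_fully_observed_identity(self, imputed_a):
        out = filter_missingness(imputed_a)
        assert out.values.equals(imputed_a.values)

    def test_matches_brute_force_recount(self, cohort_a):
        beta, _, _ = cohort_a
        kept = set(filter_missingness(beta, max_missing=0.04).probe_ids)
        expected = {
            p for p in beta.probe_ids
            if beta.values.loc[p].isna().sum() / beta.values.shape[1] <= 0.04
        }
        assert kept == expected

    def test_all_dropped_is_error(self):
        vals = pd.DataFrame(np.nan, index=["p1"], columns=["a", "b"])
        vals.iloc[0, 0] = 0.5
        with pytest.raises(ValueError):
            filter_missingness(BetaMatrix(vals), max_missing=0.2)


class TestKnnImpute:
    def test_zero_distance_neighbor_wins(self):
        vals = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.1, 0.2, np.nan], [0.9, 0.9, 0.9]],
            index=["dup", "holey", "far"], columns=["a", "b", "c"],
        )
        out = knn_impute(BetaMatrix(vals), k=1)
        assert out.values.loc["holey", "c"] == pytest.approx(0.3)

    def test_constant_matrix_stays_constant(self):
        vals = pd.DataFrame(np.full((5, 4), 0.4), index=list("abcde"), columns=list("wxyz"))
        vals.iloc[2, 1] = np.nan
        out = knn_impute(BetaMatrix(vals), k=3)
        assert np.allclose(out.values.to_numpy(), 0.4)

    def test_idempotent_on_complete_matrix(self, imputed_a):
        again = knn_impute(imputed_a)
        assert again.values.equals(imputed_a.values)

    def test_beats_column_mean_imputation(self, cohort_a, rng):
        beta, ann, _ = cohort_a
        full = knn_impute(filter_missingness(beta))
        vals = full.values.to_numpy().copy()
        # mask 50 known entries and compare recovery errors
        idx = rng.choice(vals.size, size=50, replace=False)
        rows, cols = np.unravel_index(idx, vals.shape)
        truth = vals[rows, cols].copy()
        masked = vals.copy()
        masked[rows, cols] = np.nan
        m = BetaMatrix(pd.DataFrame(masked, index=full.values.index, columns=full.values.columns))
        knn_err = np.abs(knn_impute(m).values.to_numpy()[rows, cols] - truth).mean()
        col_mean = np.nanmean(masked, axis=0)
        mean_err = np.abs(col_mean[cols] - truth).mean()
        assert knn_err < mean_err

    def test_k_too_large_is_error(self):
        vals = pd.DataFrame(np.full((3, 2), 0.5), index=list("abc"), columns=list("xy"))
        with pytest.raises(ValueError):
            knn_impute(BetaMatrix(vals), k=3)


class TestCallDifferential:
    def test_forced_large_effect_is_flagged(self):
        vals = pd.DataFrame(
            np.r_[np.full((1, 5), 0.9), np.full((1, 5), 0.5)].reshape(1, 10) * 0 + 0.5,
            index=["p"], columns=[f"s{i}" for i in range(10)],
        )
        vals.iloc[0, :5] = 0.9
        m = BetaMatrix(vals)
        out = call_differential(m, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)])
        assert out["beta_d"].iloc[0] == pytest.approx(0.4)
        assert bool(out["is_differential"].iloc[0])

    def test_identical_groups_not_flagged(self):
        block = np.array([[0.2, 0.5, 0.8], [0.3, 0.4, 0.6], [0.1, 0.9, 0.5]])
        vals = pd.DataFrame(
            np.hstack([block, block]),
            index=["p1", "p2", "p3"], columns=[f"s{i}" for i in range(6)],
        )
        out = call_differential(BetaMatrix(vals), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(out["beta_d"], 0.0)
        assert not out["is_differential"].any()

    def test_pvalues_match_t_cdf_oracle(self, imputed_a, cohort_a):
        """Per-probe p-values agree with a closed-form pooled-t oracle to 1e-9
        and the flagged set matches a brute-force dual-threshold recheck."""
        beta, _, _ = cohort_a
        cases, controls = group_ids(beta, "tumor"), group_ids(beta, "normal")
        out = call_differential(imputed_a, cases, controls)

        a = imputed_a.values[cases].to_numpy()
        b = imputed_a.values[controls].to_numpy()
        n1, n2 = a.shape[1], b.shape[1]
        sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2)
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        p_oracle = 2 * special.stdtr(df, -np.abs(t))
        assert np.allclose(out["p_value"].to_numpy(), p_oracle, atol=1e-9, rtol=0)

        # manual Benjamini-Hochberg + dual-threshold recheck
        m_tests = len(p_oracle)
        order = np.argsort(p_oracle, kind="stable")
        bh = p_oracle[order] * m_tests / np.arange(1, m_tests + 1)
        bh = np.minimum.accumulate(bh[::-1])[::-1]
        fdr = np.empty(m_tests)
        fdr[order] = np.minimum(bh, 1.0)
        expected_flags = (np.abs(out["beta_d"].to_numpy()) >= 0.2) & (fdr < 0.05)
        assert np.array_equal(out["is_differential"].to_numpy(), expected_flags)

    def test_invariant_to_sample_and_probe_order(self, imputed_a, cohort_a, rng):
        beta, _, _ = cohort_a
        cases, controls = group_ids(beta, "tumor"), group_ids(beta, "normal")
        base = call_differential(imputed_a, cases, controls).set_index("probe_id")
        shuffled = BetaMatrix(
            imputed_a.values.sample(frac=1, axis=0, random_state=7)
            .sample(frac=1, axis=1, random_state=8),
            dict(imputed_a.sample_groups),
        )
        perm = call_differential(shuffled, cases, controls).set_index("probe_id")
        perm = perm.loc[base.index]
        assert np.allclose(base["p_value"], perm["p_value"])
        assert base["is_differential"].equals(perm["is_differential"])

    def test_group_overlap_is_error(self, imputed_a):
        ids = imputed_a.sample_ids
        with pytest.raises(ValueError):
            call_differential(imputed_a, ids[:5], ids[4:9])

    def test_zero_variance_probe_gets_p_one(self):
        vals = pd.DataFrame(np.full((2, 8), 0.3), index=["z", "z2"],
                            columns=[f"s{i}" for i in range(8)])
        out = call_differential(BetaMatrix(vals), [f"s{i}" for i in range(4)],
                                [f"s{i}" for i in range(4, 8)])
        assert (out["p_value"] == 1.0).all()


class TestSitesToGenes:
    def test_deduplicates_genes(self):
        dt = pd.DataFrame({
            "probe_id": ["p1", "p2", "p3"],
            "gene_symbol": ["G1", "G1", "G2"],
            "is_differential": [True, True, False],
        })
        assert sites_to_genes(dt) == {"G1"}

    def test_no_flags_gives_empty_set(self):
        dt = pd.DataFrame({"probe_id": ["p"], "gene_symbol": ["G"], "is_differential": [False]})
        assert sites_to_genes(dt) == set()

    def test_noiseless_preset_recovers_planted_exactly(self):
        """With near-zero noise and no missingness, tumor-vs-normal calling
        recovers exactly the planted differential genes (keys + decoys)."""
        spec = luminal_a_preset(seed=5, missing_rate=0.0, beta_noise=5e5)
        beta, ann, truth = generate_cohort(spec)
        cases, controls = group_ids(beta, "tumor"), group_ids(beta, "normal")
        out = call_differential(beta, cases, controls, annotation=ann)
        genes = sites_to_genes(out)
        planted = set(truth.planted_module_of_gene)
        assert genes == planted
        assert set(truth.key_gene_ids) <= genes


def test_gene_promoter_matrix_averages_probes(cohort_a, imputed_a):
    _, ann, truth = cohort_a
    gm = gene_promoter_matrix(imputed_a, ann, genes=set(truth.key_gene_ids))
    gene = truth.key_gene_ids[0]
    probes = ann.table.loc[ann.table["gene_symbol"] == gene, "probe_id"]
    expected = imputed_a.values.loc[probes].mean(axis=0)
    assert np.allclose(gm.loc[gene], expected)
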