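"""Generator properties: HWE, ordering balance, LD, planted effect sizes."""

import numpy as np
import pandas as pd
import pytest

from poemeth.exceptions import ConsistencyError, GenerationError, SpecificationError
from poemeth.simdata import (
    COVARIATE_COLUMNS,
    SnpPanelSpec,
    TruthRecord,
    simulate_covariates,
    simulate_duo_genotypes,
    simulate_methylation,
    write_fixture,
)
from poemeth.transmission import build_codes


class TestDuoGenotypes:
    def test_child_het_fraction_matches_hwe(self):
        spec = SnpPanelSpec(n_snps=4, maf=0.25)
        duos, _ = simulate_duo_genotypes(spec, 10_000, seed=0)
        het = (duos.child == 1).mean(axis=0)
        expected = 2 * 0.25 * 0.75
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert np.all(np.abs(het - expected) < 4 * se)

    def test_heterozygote_orderings_balanced(self):
        spec = SnpPanelSpec(n_snps=4, maf=0.3)
        duos, truth_P = simulate_duo_genotypes(spec, 10_000, seed=1)
        het = duos.child == 1
        frac_mat = (truth_P[het] == 1).mean()
        assert abs(frac_mat - 0.5) < 4 / np.sqrt(het.sum())

    def test_perfect_ld_block_gives_identical_columns(self):
        spec = SnpPanelSpec(n_snps=4, maf=0.2, ld_blocks=[(2, 1.0)])
        duos, _ = simulate_duo_genotypes(spec, 500, seed=2)
        assert np.array_equal(duos.child[:, 0], duos.child[:, 1])
        assert np.array_equal(duos.mother[:, 0], duos.mother[:, 1])
        # the remaining SNPs are independent of the block
        r = np.corrcoef(duos.child[:, 0], duos.child[:, 2])[0, 1]
        assert abs(r) < 3 / np.sqrt(500)

    def test_ld_block_intermediate_r_raises_genotype_correlation(self):
        spec = SnpPanelSpec(n_snps=2, maf=0.3, ld_blocks=[(2, 0.9)])
        duos, _ = simulate_duo_genotypes(spec, 5_000, seed=3)
        r = np.corrcoef(duos.child[:, 0], duos.child[:, 1])[0, 1]
        assert r > 0.5

    def test_mendelian_consistency_by_construction(self):
        spec = SnpPanelSpec(n_snps=6, maf=0.4)
        duos, _ = simulate_duo_genotypes(spec, 2_000, seed=4)
        _, flags = __import__("poemeth").transmission.resolve_duo_transmission_matrix(
            duos.child, duos.mother
        )
        assert not flags.any()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 2, "maf": 0.01},
            {"n_snps": 2, "maf": 0.6},
            {"n_snps": 2, "pos": np.array([100, 100])},
            {"n_snps": 2, "ld_blocks": [(3, 0.5)]},
        ],
    )
    def test_invalid_panel_specs_rejected(self, kwargs):
        with pytest.raises(SpecificationError):
            SnpPanelSpec(**kwargs)

    def test_zero_duos_rejected(self):
        with pytest.raises(SpecificationError):
            simulate_duo_genotypes(SnpPanelSpec(n_snps=2), 0, seed=0)


class TestCovariates:
    def test_fifteen_columns_no_missing(self):
        covs = simulate_covariates(100, seed=0)
        assert list(covs.table.columns) == COVARIATE_COLUMNS
        assert covs.matrix.shape == (100, 15)

    def test_seeded_regeneration_is_bit_identical(self):
        a = simulate_covariates(50, seed=7)
        b = simulate_covariates(50, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_cohort_rejected(self):
        with pytest.raises(SpecificationError):
            simulate_covariates(0, seed=0)


class TestMethylation:
    def test_null_cpg_uncorrelated_with_poe_coding(self, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        j = list(duos.snp_meta["id"]).index("rs5")
        y = mm.values.loc["cg_null"].to_numpy(float)
        r = np.corrcoef(y, truth_P[:, j])[0, 1]
        assert abs(r) < 3 / np.sqrt(duos.n_duos)

    def test_realized_poe_r2_recovers_request_across_grid(self):
        """Across the variance grid the realized partial R2 of beta on the
        true POE coding matches the request within Monte-Carlo error."""
        spec = SnpPanelSpec(n_snps=1, maf=0.25)
        for r2 in (0.005, 0.01, 0.02, 0.04, 0.09):
            realized = []
            for rep in range(10):
                duos, truth_P = simulate_duo_genotypes(spec, 2_000, seed=100 + rep)
                covs = simulate_covariates(2_000, seed=200 + rep, samples=duos.samples)
                truth = [TruthRecord("cg", "rs1", "uniparental_maternal", r2)]
                mm = simulate_methylation(duos, truth, covs, seed=300 + rep)
                y = mm.values.loc["cg"].to_numpy(float)
                # residualize covariates, then squared correlation with truth
                X = np.column_stack([np.ones(2_000), covs.matrix])
                resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
                realized.append(np.corrcoef(resid, truth_P[:, 0])[0, 1] ** 2)
            realized = np.asarray(realized)
            se = realized.std(ddof=1) / np.sqrt(realized.size)
            assert abs(realized.mean() - r2) < 2 * se + 2.0 / 2_000

    def test_uniparental_realized_partial_r_scale(self):
        spec = SnpPanelSpec(n_snps=1, maf=0.25)
        duos, truth_P = simulate_duo_genotypes(spec, 5_000, seed=11)
        covs = simulate_covariates(5_000, seed=12, samples=duos.samples)
        mm = simulate_methylation(
            duos, [TruthRecord("cg", "rs1", "uniparental_maternal", 0.09)], covs, seed=13
        )
        y = mm.values.loc["cg"].to_numpy(float)
        X = np.column_stack([np.ones(5_000), covs.matrix])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r = np.corrcoef(resid, truth_P[:, 0])[0, 1]
        assert abs(abs(r) - 0.30) < 0.03  # sqrt(0.09)

    def test_uniparental_group_structure(self, planted_cohort):
        """One heterozygote ordering tracks each homozygote group."""
        duos, truth_P, covs, truth, mm = planted_cohort
        y = mm.values.loc["cg_uni"].to_numpy(float)
        P = truth_P[:, 0]
        A = duos.child[:, 0]
        m = {
            "hom_major": y[A == 0].mean(),
            "hom_minor": y[A == 2].mean(),
            "het_mat": y[P == 1].mean(),
            "het_pat": y[P == -1].mean(),
        }
        tol = 3 * y.std() / np.sqrt(100)
        assert abs(m["het_mat"] - m["hom_minor"]) < tol
        assert abs(m["het_pat"] - m["hom_major"]) < tol
        assert abs(m["hom_minor"] - m["hom_major"]) > 2 * tol

    def test_bipolar_group_structure(self, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        j = list(duos.snp_meta["id"]).index("rs3")
        y = mm.values.loc["cg_bip"].to_numpy(float)
        P, A = truth_P[:, j], duos.child[:, j]
        hom_mean = y[A != 1].mean()
        sd = y.std()
        se_homs = sd * np.sqrt(1 / (A == 0).sum() + 1 / (A == 2).sum())
        se_het = sd * np.sqrt(1 / (P == 1).sum() + 1 / (A != 1).sum())
        assert abs(y[A == 0].mean() - y[A == 2].mean()) < 4 * se_homs
        assert y[P == 1].mean() - hom_mean > 3 * se_het
        assert hom_mean - y[P == -1].mean() > 3 * se_het

    def test_values_in_unit_interval_and_low_clipping(self, planted_cohort):
        *_, mm = planted_cohort
        vals = mm.values.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        assert mm.clipping_rate < 0.01

    def test_infeasible_poe_r2_raises(self, cohort740):
        duos, _, covs = cohort740
        with pytest.raises(GenerationError):
            simulate_methylation(
                duos, [TruthRecord("cg", "rs1", "uniparental_maternal", 0.8)], covs, seed=0
            )

    def test_unknown_target_snp_raises(self, cohort740):
        duos, _, covs = cohort740
        with pytest.raises(ConsistencyError):
            simulate_methylation(
                duos, [TruthRecord("cg", "rs99", "null", 0.0)], covs, seed=0
            )

    def test_heteroscedastic_noise_tracks_group_mean(self):
        spec = SnpPanelSpec(n_snps=1, maf=0.3)
        duos, truth_P = simulate_duo_genotypes(spec, 20_000, seed=21)
        mm = simulate_methylation(
            duos,
            [TruthRecord("cg", "rs1", "uniparental_maternal", 0.3,
                         noise_model="heteroscedastic")],
            None,
            seed=22,
            baseline=0.15,
            noise_sd=0.05,
        )
        y = mm.values.loc["cg"].to_numpy(float)
        mat = duos.child_phase[:, 0, 1] == 1
        # the low-methylation group sits nearer 0 -> smaller noise SD
        assert y[~mat].std() < y[mat].std()

    def test_null_statistics_symmetric_under_ordering_labels(self):
        """Exchangeability: at null CpGs the POE effect distribution over
        many CpGs is symmetric around zero."""
        spec = SnpPanelSpec(n_snps=1, maf=0.25)
        duos, truth_P = simulate_duo_genotypes(spec, 1_000, seed=31)
        truth = [TruthRecord(f"cg{i}", "rs1", "null", 0.0) for i in range(200)]
        mm = simulate_methylation(duos, truth, None, seed=32)
        P = truth_P[:, 0]
        betas = []
        for i in range(200):
            y = mm.values.iloc[i].to_numpy(float)
            betas.append(np.dot(y - y.mean(), P) / np.dot(P, P))
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 2 * betas.std(ddof=1) / np.sqrt(betas.size)


class TestFixtureRoundTrip:
    def test_write_then_read_recovers_everything(self, tmp_path, planted_cohort):
        from poemeth import io as pio

        duos, truth_P, covs, truth, mm = planted_cohort
        paths = write_fixture(duos, mm, covs, truth, tmp_path)
        d2 = pio.read_duo_vcf(paths["child_vcf"], paths["mother_vcf"], paths["ped"])
        assert np.array_equal(duos.child, d2.child)
        assert np.array_equal(duos.mother, d2.mother)
        # phased VCF allele order encodes the truth transmissions
        codes = build_codes(d2)
        assert np.array_equal(codes.P, truth_P)
        m2 = pio.read_methylation_matrix(
            paths["methylation_childhood"], paths["cpg_bed"], d2.samples
        )
        assert np.allclose(
            m2.values.to_numpy(), mm.values.to_numpy(), atol=5e-6
        )

    def test_sample_mismatch_rejected(self, tmp_path, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        bad = simulate_covariates(10, seed=0)
        with pytest.raises(ConsistencyError):
            write_fixture(duos, mm, bad, truth, tmp_path)
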