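"""Regression engine: oracles against normal equations, sandwich arithmetic
and statsmodels; invariances of the POE contrast."""

import numpy as np
import pandas as pd
import pytest

from poemeth.exceptions import DegenerateDesignError
from poemeth.poescan import (
    ScanConfig,
    cis_pairs,
    fit_poe_model,
    hc_covariance,
    partial_correlation,
    run_scan,
)
from poemeth.simdata import TruthRecord, simulate_methylation
from poemeth.transmission import build_codes


def _hand_dataset(seed=0, n_covs=0):
    """12 observations, 3 per design row, mild noise."""
    rng = np.random.default_rng(seed)
    A = np.repeat([0.0, 1.0, 1.0, 2.0], 3)
    P = np.repeat([0.0, 1.0, -1.0, 0.0], 3)
    D = (A == 1).astype(float)
    covs = rng.standard_normal((12, n_covs)) if n_covs else None
    y = 0.4 + 0.05 * A + 0.02 * D + 0.08 * P + rng.normal(0, 0.02, 12)
    if covs is not None:
        y = y + covs @ rng.normal(0, 0.01, n_covs)
    return y, A, D, P, covs


class TestCisPairs:
    def test_inclusive_boundary(self):
        cpgs = pd.DataFrame({"cpg_id": ["c1"], "chrom": ["1"], "pos": [1_000_000]})
        snps = pd.DataFrame(
            {"id": ["s1", "s2"], "chrom": ["1", "1"], "pos": [1_500_000, 1_500_001]}
        )
        pairs = cis_pairs(cpgs, snps, window=500_000)
        assert pairs["snp_id"].tolist() == ["s1"]

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(3)],
                "chrom": rng.choice(["1", "2"], 3),
                "pos": rng.integers(1, 3_000_000, 3),
            }
        )
        snps = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(5)],
                "chrom": rng.choice(["1", "2"], 5),
                "pos": rng.integers(1, 3_000_000, 5),
            }
        )
        got = set(map(tuple, cis_pairs(cpgs, snps, 500_000).to_numpy()))
        expected = {
            (c.cpg_id, s.id)
            for c in cpgs.itertuples()
            for s in snps.itertuples()
            if c.chrom == s.chrom and abs(c.pos - s.pos) <= 500_000
        }
        assert got == expected


class TestFit:
    def test_exact_linear_case(self, balanced_codes):
        A, D, P = balanced_codes(n_major=6, n_minor=4, n_het_each=5)
        y = 0.5 + 0.1 * P
        res = fit_poe_model(y, A, D, P)
        assert res.betaP == pytest.approx(0.1, abs=1e-12)
        assert res.beta0 == pytest.approx(0.5, abs=1e-12)
        assert abs(res.betaA) < 1e-12 and abs(res.betaD) < 1e-12

    def test_coefficients_match_normal_equations(self):
        y, A, D, P, covs = _hand_dataset(n_covs=2)
        res = fit_poe_model(y, A, D, P, covs, ScanConfig(min_het=3))
        X = np.column_stack([np.ones(12), A, D, P, covs])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        got = np.array([res.beta0, res.betaA, res.betaD, res.betaP, *res.cov_betas])
        assert np.allclose(got, beta, atol=1e-10)

    @pytest.mark.parametrize("se_type", ["HC0", "HC1", "HC3"])
    def test_sandwich_matches_statsmodels(self, se_type):
        import statsmodels.api as sm

        y, A, D, P, covs = _hand_dataset(seed=3, n_covs=2)
        res = fit_poe_model(y, A, D, P, covs, ScanConfig(se_type=se_type))
        X = np.column_stack([np.ones(12), A, D, P, covs])
        fit = sm.OLS(y, X).fit(cov_type=se_type)
        assert res.robust_se_P == pytest.approx(fit.bse[3], rel=1e-10)
        assert res.betaP == pytest.approx(fit.params[3], rel=1e-10)

    def test_all_homozygotes_is_degenerate(self):
        y = np.linspace(0.2, 0.8, 10)
        A = np.repeat([0.0, 2.0], 5)
        P = np.zeros(10)
        with pytest.raises(DegenerateDesignError):
            fit_poe_model(y, A, (A == 1).astype(float), P)

    def test_min_het_enforced(self, balanced_codes):
        A, D, P = balanced_codes(n_het_each=2)
        with pytest.raises(DegenerateDesignError):
            fit_poe_model(np.random.default_rng(0).random(A.size), A, D, P,
                          config=ScanConfig(min_het=3))

    def test_rank_deficiency_detected(self, balanced_codes):
        A, D, P = balanced_codes(n_major=6, n_minor=4, n_het_each=5)
        dup = A.reshape(-1, 1).copy()  # covariate identical to A
        with pytest.raises(DegenerateDesignError):
            fit_poe_model(0.5 + 0.1 * P, A, D, P, dup)


class TestSandwich:
    def test_zero_residuals_give_zero_matrix(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        assert np.allclose(hc_covariance(X, np.zeros(6), "HC3"), 0.0)

    @pytest.mark.parametrize("se_type", ["HC0", "HC1", "HC3"])
    def test_five_point_toy_matches_elementwise_arithmetic(self, se_type):
        """Independent oracle: the sandwich assembled with explicit loops."""
        X = np.array([[1, 0.0], [1, 1.0], [1, 2.0], [1, 3.0], [1, 4.0]])
        y = np.array([0.1, 0.3, 0.2, 0.6, 0.5])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        e = y - X @ beta
        n, k = X.shape
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((k, k))
        for i in range(n):
            h_i = X[i] @ bread @ X[i]
            if se_type == "HC0":
                w = 1.0
            elif se_type == "HC1":
                w = n / (n - k)
            else:
                w = (1 - h_i) ** -2
            meat += w * e[i] ** 2 * np.outer(X[i], X[i])
        expected = bread @ meat @ bread
        assert np.allclose(hc_covariance(X, e, se_type), expected, atol=1e-12)

    def test_homoscedastic_large_sample_agrees_with_classical(self):
        rng = np.random.default_rng(8)
        n = 20_000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([0.2, 0.5]) + rng.normal(0, 0.3, n)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        robust = np.sqrt(np.diag(hc_covariance(X, e, "HC3")))
        classical = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * (e @ e) / (n - 2))
        assert np.all(np.abs(robust / classical - 1) < 0.05)


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_pearson(self):
        rng = np.random.default_rng(1)
        y = rng.random(50)
        P = rng.choice([-1.0, 0.0, 1.0], 50)
        assert partial_correlation(y, None, P) == pytest.approx(
            np.corrcoef(y - y.mean(), P)[0, 1]
        )

    def test_orthogonal_covariates_leave_value_unchanged(self):
        rng = np.random.default_rng(2)
        n = 400
        y = rng.random(n)
        P = rng.choice([-1.0, 0.0, 1.0], n)
        # covariates constructed orthogonal to y and P by residualization
        C = rng.standard_normal((n, 3))
        B = np.column_stack([np.ones(n), y, P])
        C = C - B @ np.linalg.lstsq(B, C, rcond=None)[0]
        assert partial_correlation(y, C, P) == pytest.approx(
            partial_correlation(y, None, P), abs=1e-10
        )

    def test_constant_inputs_reported_missing(self):
        assert np.isnan(partial_correlation(np.ones(10), None, np.zeros(10)))


class TestInvariances:
    def test_label_flip_negates_beta_and_preserves_p(self, balanced_codes):
        rng = np.random.default_rng(3)
        A, D, P = balanced_codes(n_major=30, n_minor=12, n_het_each=20)
        y = 0.5 + 0.03 * P + rng.normal(0, 0.05, A.size)
        a = fit_poe_model(y, A, D, P)
        b = fit_poe_model(y, A, D, -P)
        assert b.betaP == pytest.approx(-a.betaP, rel=1e-12)
        assert b.wald_p_P == pytest.approx(a.wald_p_P, rel=1e-12)

    def test_betaP_unchanged_without_A_D_when_balanced(self, balanced_codes):
        rng = np.random.default_rng(4)
        A, D, P = balanced_codes(n_major=40, n_minor=16, n_het_each=25)
        y = 0.5 + 0.04 * A + 0.02 * D + 0.05 * P + rng.normal(0, 0.05, A.size)
        full = fit_poe_model(y, A, D, P)
        slope_p_only = np.dot(y - y.mean(), P) / np.dot(P, P)
        assert full.betaP == pytest.approx(slope_p_only, abs=1e-10)


class TestRunScan:
    def test_row_count_is_timepoints_times_cis_pairs(self, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        codes = build_codes(duos)
        meths = {}
        for k, tp in enumerate(["birth", "childhood", "adolescence"]):
            m2 = simulate_methylation(duos, truth, covs, seed=50 + k, time_point=tp)
            meths[tp] = m2
        res = run_scan(meths, codes, covs, ScanConfig(), duos.snp_meta)
        pairs = cis_pairs(meths["birth"].coords, duos.snp_meta, 500_000)
        assert len(res) == 3 * len(pairs)

    def test_scan_is_deterministic(self, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        codes = build_codes(duos)
        r1 = run_scan(mm, codes, covs, ScanConfig(), duos.snp_meta)
        r2 = run_scan(mm, codes, covs, ScanConfig(), duos.snp_meta)
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_pairs_recorded_not_raised(self, planted_cohort):
        duos, truth_P, covs, truth, mm = planted_cohort
        codes = build_codes(duos)
        codes.P[:, 0] = 0.0  # no resolvable heterozygotes at rs1
        res = run_scan(mm, codes, covs, ScanConfig(), duos.snp_meta)
        sub = res[res["snp_id"] == "rs1"]
        assert len(sub) and sub["degenerate"].all()
        assert not res[res["snp_id"] != "rs1"]["degenerate"].any()
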