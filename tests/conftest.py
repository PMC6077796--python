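"""Shared fixtures: small simulated duo cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from poemeth.simdata import (
    SnpPanelSpec,
    TruthRecord,
    simulate_covariates,
    simulate_duo_genotypes,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def cohort740():
    """A study-sized cohort: 740 duos, 8 SNPs at MAF 0.25."""
    spec = SnpPanelSpec(n_snps=8, maf=0.25)
    duos, truth_P = simulate_duo_genotypes(spec, 740, seed=0)
    covs = simulate_covariates(740, seed=1, samples=duos.samples)
    return duos, truth_P, covs


@pytest.fixture(scope="session")
def planted_cohort(cohort740):
    """Cohort with one uniparental, one bipolar and one null CpG planted."""
    duos, truth_P, covs = cohort740
    truth = [
        TruthRecord("cg_uni", "rs1", "uniparental_maternal", 0.09),
        TruthRecord("cg_bip", "rs3", "bipolar", 0.09),
        TruthRecord("cg_null", "rs5", "null", 0.0),
    ]
    mm = simulate_methylation(duos, truth, covs, seed=2)
    return duos, truth_P, covs, truth, mm


@pytest.fixture
def balanced_codes():
    """Factory for samples with exactly balanced heterozygote orderings."""

    def make(n_major=4, n_minor=2, n_het_each=3):
        A = np.array([0.0] * n_major + [2.0] * n_minor + [1.0] * (2 * n_het_each))
        P = np.array(
            [0.0] * (n_major + n_minor) + [1.0] * n_het_each + [-1.0] * n_het_each
        )
        D = (A == 1).astype(float)
        return A, D, P

    return make
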