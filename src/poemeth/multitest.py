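"""Effective number of independent tests and the genome-wide threshold.

Neighbouring SNPs are correlated through LD, so a Bonferroni correction over
the raw test count is too harsh.  The effective test count is estimated from
the eigenvalue spectrum of the SNP correlation matrix in randomly sampled
genomic windows; the ratio Meff/M, averaged over windows, rescales the total
number of tests before the Bonferroni division.

Two spectral estimators are provided:

* ``li_ji``:   Meff = sum_i [ 1{lambda_i >= 1} + (lambda_i - floor(lambda_i)) ]
* ``nyholt``:  Meff = 1 + (M - 1) * (1 - Var(lambda) / M)

both satisfying Meff = M for independent SNPs and Meff = 1 for perfectly
correlated ones.  li_ji is the default; it is also exactly additive over
block-diagonal correlation structure (the spectrum of a block-diagonal
matrix is the union of the block spectra), which nyholt is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import SpecificationError

__all__ = [
    "EffectiveTestEstimate",
    "meff_spectral",
    "estimate_genomewide_ratio",
    "bonferroni_threshold",
]

METHODS = ("li_ji", "nyholt")


@dataclass
class EffectiveTestEstimate:
    """Spectral effective-test estimate for one correlation matrix."""

    M: int
    eigenvalues: np.ndarray
    Meff: float
    method: str = "li_ji"

    @property
    def ratio(self) -> float:
        return self.Meff / self.M


@dataclass
class GenomewideRatio:
    """Mean Meff/M ratio over sampled windows with a normal-theory 95% CI."""

    ratio: float
    ci_low: float
    ci_high: float
    per_window: np.ndarray = field(default_factory=lambda: np.array([]))
    n_windows: int = 0


def meff_spectral(corr: np.ndarray, method: str = "li_ji") -> EffectiveTestEstimate:
    """Effective number of independent tests from a SNP correlation matrix.

    ``corr`` must be symmetric with unit diagonal; small negative
    eigenvalues from pairwise-complete estimation are tolerated to 1e-8 and
    clipped, anything beyond that raises.
    """
    if method not in METHODS:
        raise SpecificationError(f"method must be one of {METHODS}")
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise SpecificationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10) or not np.allclose(np.diag(corr), 1.0):
        raise SpecificationError("correlation matrix must be symmetric with unit diagonal")
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise SpecificationError("matrix is not positive semi-definite beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    M = corr.shape[0]
    if method == "li_ji":
        meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    else:
        var = lam.var(ddof=1) if M > 1 else 0.0
        meff = 1.0 + (M - 1) * (1.0 - var / M)
    return EffectiveTestEstimate(M=M, eigenvalues=lam, Meff=meff, method=method)


def estimate_genomewide_ratio(
    genotypes: np.ndarray,
    positions: np.ndarray,
    seed: int | np.random.SeedSequence,
    n_windows: int = 100,
    window: int = 1_000_000,
    method: str = "li_ji",
) -> GenomewideRatio:
    """Mean Meff/M over randomly placed windows of ``window`` bp.

    ``genotypes`` is a sample x SNP minor-allele-count matrix (NaN for
    missing; correlations are pairwise-complete), ``positions`` the matching
    1-based coordinates (single chromosome or concatenated coordinates).
    Windows with fewer than 2 SNPs are skipped and re-drawn; the estimate
    is the across-window mean with a normal-theory 95% CI.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions)
    lo, hi = positions.min(), positions.max()
    if hi - lo < window:
        raise SpecificationError("genotype panel narrower than one window")
    ratios = []
    attempts = 0
    while len(ratios) < n_windows and attempts < 50 * n_windows:
        attempts += 1
        start = rng.integers(lo, hi - window + 1)
        sel = (positions >= start) & (positions < start + window)
        if sel.sum() < 2:
            continue
        sub = genotypes[:, sel].astype(float)
        est = meff_spectral(_pairwise_corr(sub), method=method)
        ratios.append(est.ratio)
    if len(ratios) < n_windows:
        raise SpecificationError("could not place the requested number of windows with >= 2 SNPs")
    ratios = np.asarray(ratios)
    se = ratios.std(ddof=1) / math.sqrt(len(ratios))
    z = norm.ppf(0.975)
    return GenomewideRatio(
        ratio=float(ratios.mean()),
        ci_low=float(ratios.mean() - z * se),
        ci_high=float(ratios.mean() + z * se),
        per_window=ratios,
        n_windows=len(ratios),
    )


def _pairwise_corr(sub: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlation with unit diagonal (constant SNPs -> 0)."""
    import pandas as pd

    corr = pd.DataFrame(sub).corr(min_periods=2).to_numpy()
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def bonferroni_threshold(
    n_tests: float, ratio: float, alpha: float = 0.05, sig_figs: int = 2
) -> float:
    """Bonferroni threshold over the effective test count.

    threshold = alpha / (ratio * n_tests), truncated (floored, not rounded)
    to ``sig_figs`` significant figures -- e.g. 0.05 / (0.33 * 4e8) =
    3.787e-10 reported as 3.7e-10 at two significant figures.
    """
    if not (0 < ratio <= 1):
        raise SpecificationError("ratio must lie in (0, 1]")
    if n_tests < 1:
        raise SpecificationError("n_tests must be >= 1")
    raw = alpha / (ratio * n_tests)
    exponent = math.floor(math.log10(raw))
    mantissa = raw / 10**exponent
    truncated = math.floor(mantissa * 10 ** (sig_figs - 1)) / 10 ** (sig_figs - 1)
    return truncated * 10**exponent
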