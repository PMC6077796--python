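"""Per CpG-SNP parent-of-origin regression scan.

For every cis CpG-SNP pair the methylation beta value is regressed on the
orthogonal genotype codings plus covariates,

    CpG = b0 + bA * A + bD * D + bP * P + sum_i bi * cov_i + e,

and the POE coefficient bP is tested with a heteroscedasticity-consistent
(White-Huber sandwich) Wald test: methylation beta values are bounded and
their residual spread varies with the mean, so classical OLS standard errors
are not trusted.  Effect sizes are additionally summarised as the partial
correlation R between the covariate-adjusted methylation residuals and the
raw POE coding.

The linear algebra is deliberately plain numpy (the scan fits millions of
small regressions); statsmodels reproduces every number here and is used as
an independent cross-check in the test-suite, not as the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .exceptions import DegenerateDesignError, SpecificationError
from .simdata import CovariateSet, MethylationMatrix
from .transmission import TransmissionCodes

__all__ = [
    "ScanConfig",
    "PoeTestResult",
    "cis_pairs",
    "hc_covariance",
    "fit_poe_model",
    "partial_correlation",
    "run_scan",
]

HC_TYPES = ("HC0", "HC1", "HC3")


@dataclass
class ScanConfig:
    """Tunable parameters of the scan.

    ``window``: cis window in bp, inclusive at the boundary (default 500 kb).
    ``se_type``: sandwich variant; HC3 by default (the small-sample
    leverage-corrected form).  ``min_het``: minimum count per heterozygote
    ordering for the POE contrast to be identifiable beyond single
    observations.  ``use_t``: refer the Wald statistic to a t(n-k) instead
    of the normal.  ``adjust_ad_in_partial``: additionally residualize A and
    D when computing the partial correlation (sensitivity option; the
    default residualizes covariates only).
    """

    window: int = 500_000
    se_type: str = "HC3"
    min_het: int = 3
    use_t: bool = False
    adjust_ad_in_partial: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.se_type not in HC_TYPES:
            raise SpecificationError(f"se_type must be one of {HC_TYPES}")
        if self.window <= 0 or self.min_het < 1:
            raise SpecificationError("window and min_het must be positive")


@dataclass
class PoeTestResult:
    """Fitted POE regression for one (CpG, SNP, time point)."""

    cpg_id: str
    snp_id: str
    time_point: str = ""
    beta0: float = np.nan
    betaA: float = np.nan
    betaD: float = np.nan
    betaP: float = np.nan
    cov_betas: np.ndarray = field(default_factory=lambda: np.array([]))
    robust_se_P: float = np.nan
    wald_p_P: float = np.nan
    wald_p_A: float = np.nan
    wald_p_D: float = np.nan
    partial_R: float = np.nan
    n_used: int = 0
    n_het_pat: int = 0
    n_het_mat: int = 0
    degenerate: bool = False


def cis_pairs(
    cpg_coords: pd.DataFrame, snp_coords: pd.DataFrame, window: int = 500_000
) -> pd.DataFrame:
    """All (CpG, SNP) pairs on the same chromosome within ``window`` bp.

    ``cpg_coords`` needs columns ``cpg_id, chrom, pos``; ``snp_coords``
    needs ``id, chrom, pos`` (1-based).  The window is inclusive: a SNP
    exactly ``window`` bp from the CpG is tested.
    """
    out = []
    snp_by_chrom = dict(tuple(snp_coords.groupby("chrom", sort=False)))
    for row in cpg_coords.itertuples(index=False):
        snps = snp_by_chrom.get(row.chrom)
        if snps is None:
            continue
        near = snps[(snps["pos"] - row.pos).abs() <= window]
        for sid in near["id"]:
            out.append((row.cpg_id, sid))
    return pd.DataFrame(out, columns=["cpg_id", "snp_id"])


def hc_covariance(
    X: np.ndarray,
    residuals: np.ndarray,
    se_type: str = "HC3",
    leverages: np.ndarray | None = None,
) -> np.ndarray:
    """Heteroscedasticity-consistent coefficient covariance.

    Computes ``(X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1`` with weights
    w_i = 1 (HC0), n/(n-k) (HC1) or (1 - h_i)^-2 (HC3), where h_i are the
    hat-matrix leverages.  Observations with leverage 1 are excluded from
    the HC3 meat (their weight is undefined); the fit itself reproduces such
    points exactly, so they carry zero residual anyway.
    """
    if se_type not in HC_TYPES:
        raise SpecificationError(f"se_type must be one of {HC_TYPES}")
    n, k = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    if se_type == "HC0":
        w = np.ones(n)
    elif se_type == "HC1":
        w = np.full(n, n / (n - k))
    else:
        if leverages is None:
            leverages = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        w = np.zeros(n)
        ok = leverages < 1.0 - 1e-12
        w[ok] = (1.0 - leverages[ok]) ** -2
    meat = (X * (w * residuals**2)[:, None]).T @ X
    return xtx_inv @ meat @ xtx_inv


def _wald_p(z: float, df: int, use_t: bool) -> float:
    if use_t:
        return 2.0 * t_dist.sf(abs(z), df)
    return 2.0 * norm.sf(abs(z))


def fit_poe_model(
    y: np.ndarray,
    A: np.ndarray,
    D: np.ndarray,
    P: np.ndarray,
    covariates: np.ndarray | None = None,
    config: ScanConfig | None = None,
    cpg_id: str = "",
    snp_id: str = "",
    time_point: str = "",
) -> PoeTestResult:
    """OLS fit of the POE model with sandwich Wald tests.

    Rows with missing methylation or an unresolved POE code are dropped.
    Requires both heterozygote orderings with at least ``min_het``
    individuals and a full-rank design; otherwise raises
    :class:`~poemeth.exceptions.DegenerateDesignError`.
    """
    cfg = config or ScanConfig()
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(P) | np.isnan(A))
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    y, A_, D_, P_ = y[keep], A[keep], D[keep], P[keep]
    n_mat = int((P_ == 1).sum())
    n_pat = int((P_ == -1).sum())
    if min(n_mat, n_pat) < cfg.min_het:
        raise DegenerateDesignError(
            f"{cpg_id}/{snp_id}: heterozygote orderings {n_pat}/{n_mat} below "
            f"min_het={cfg.min_het}"
        )
    cols = [np.ones(y.size), A_, D_, P_]
    if covariates is not None:
        cols.append(covariates[keep])
    X = np.column_stack(cols)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise DegenerateDesignError(f"{cpg_id}/{snp_id}: rank-deficient design ({rank} < {k})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    vcov = hc_covariance(X, resid, cfg.se_type)
    se = np.sqrt(np.diag(vcov))
    zP = beta[3] / se[3]
    zA = beta[1] / se[1]
    zD = beta[2] / se[2]
    covmat = covariates[keep] if covariates is not None else None
    R = partial_correlation(y, covmat, P_, A=A_ if cfg.adjust_ad_in_partial else None,
                            D=D_ if cfg.adjust_ad_in_partial else None)
    return PoeTestResult(
        cpg_id=cpg_id,
        snp_id=snp_id,
        time_point=time_point,
        beta0=beta[0],
        betaA=beta[1],
        betaD=beta[2],
        betaP=beta[3],
        cov_betas=beta[4:].copy(),
        robust_se_P=se[3],
        wald_p_P=_wald_p(zP, n - k, cfg.use_t),
        wald_p_A=_wald_p(zA, n - k, cfg.use_t),
        wald_p_D=_wald_p(zD, n - k, cfg.use_t),
        partial_R=R,
        n_used=n,
        n_het_pat=n_pat,
        n_het_mat=n_mat,
    )


def partial_correlation(
    y: np.ndarray,
    covariates: np.ndarray | None,
    P: np.ndarray,
    A: np.ndarray | None = None,
    D: np.ndarray | None = None,
) -> float:
    """Pearson correlation between covariate-adjusted methylation and raw P.

    Methylation is residualized on intercept + covariates only (A and D are
    deliberately not removed unless passed explicitly); the POE coding
    enters raw.  Returns nan when either side has zero variance.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.ones(y.size)]
    if covariates is not None:
        cols.append(covariates)
    if A is not None:
        cols.append(A)
    if D is not None:
        cols.append(D)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if resid.std() == 0 or np.std(P) == 0:
        return np.nan
    return float(np.corrcoef(resid, P)[0, 1])


def run_scan(
    methylation: MethylationMatrix | dict[str, MethylationMatrix],
    codes: TransmissionCodes,
    covs: CovariateSet | None = None,
    config: ScanConfig | None = None,
    snp_coords: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the POE model over all cis pairs and time points.

    ``snp_coords`` defaults to positions inferred from ``codes.snp_ids``
    being present in the methylation coordinate frame; normally pass
    ``duos.snp_meta``.  Degenerate pairs are recorded with missing p-values
    rather than aborting the scan.  Deterministic given its inputs.
    """
    cfg = config or ScanConfig()
    meths = methylation if isinstance(methylation, dict) else {methylation.time_point: methylation}
    covmat = covs.matrix if covs is not None else None
    snp_pos = {} if snp_coords is None else dict(zip(snp_coords["id"], snp_coords["pos"]))
    snp_idx = {s: j for j, s in enumerate(codes.snp_ids)}
    rows = []
    for tp, mm in meths.items():
        if list(mm.values.columns) != list(codes.samples):
            raise SpecificationError(f"sample mismatch between codes and methylation [{tp}]")
        if snp_coords is not None:
            pairs = cis_pairs(mm.coords, snp_coords, cfg.window)
        else:
            pairs = pd.DataFrame(
                [(c, s) for c in mm.cpg_ids for s in codes.snp_ids],
                columns=["cpg_id", "snp_id"],
            )
        cpg_pos = dict(zip(mm.coords["cpg_id"], mm.coords["pos"]))
        cpg_chrom = dict(zip(mm.coords["cpg_id"], mm.coords["chrom"]))
        yvals = mm.values
        for cpg_id, snp_id in pairs.itertuples(index=False):
            j = snp_idx[snp_id]
            y = yvals.loc[cpg_id].to_numpy(dtype=float)
            try:
                res = fit_poe_model(
                    y, codes.A[:, j], codes.D[:, j], codes.P[:, j], covmat, cfg,
                    cpg_id=cpg_id, snp_id=snp_id, time_point=tp,
                )
            except DegenerateDesignError:
                res = PoeTestResult(cpg_id=cpg_id, snp_id=snp_id, time_point=tp, degenerate=True)
            rows.append(
                {
                    "cpg_id": res.cpg_id,
                    "snp_id": res.snp_id,
                    "time_point": tp,
                    "chrom": cpg_chrom.get(cpg_id),
                    "cpg_pos": cpg_pos.get(cpg_id),
                    "snp_pos": snp_pos.get(snp_id),
                    "n_used": res.n_used,
                    "n_het_pat": res.n_het_pat,
                    "n_het_mat": res.n_het_mat,
                    "betaA": res.betaA,
                    "betaD": res.betaD,
                    "betaP": res.betaP,
                    "se_P": res.robust_se_P,
                    "p_A": res.wald_p_A,
                    "p_D": res.wald_p_D,
                    "p_P": res.wald_p_P,
                    "partial_R": res.partial_R,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)
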