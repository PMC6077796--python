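"""Methylation-based inference of parental transmission in heterozygotes.

At a uniparentally imprinted CpG one parental chromosome is silenced, so the
methylation mean of one heterozygote ordering coincides with the minor-allele
homozygotes and the other with the major-allele homozygotes.  A logistic
model fitted to the *homozygous* individuals only,

    logit Pr(H = 1) = b0 + b1 * CpG,      H = 0 minor hom, 1 major hom,

therefore transfers to heterozygotes: the predicted probability P of
resembling the major-homozygote group splits heterozygotes into the two
orderings, and P - (1 - P) = 2P - 1 is a probability-weighted ("expected
dosage") POE code.  Class imbalance between the homozygote groups (severe at
low MAF, where minor homozygotes are rare) is deliberately not corrected:
the trained intercept absorbs the homozygote prior odds, exactly as the
plain fit produces it.

Accuracy is summarised per SNP by the rank-based (Mann-Whitney) AUC over
heterozygotes with known truth, with half-credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .exceptions import InputError

__all__ = [
    "HomozygoteModel",
    "TransmissionInference",
    "fit_homozygote_model",
    "predict_transmission",
    "transmission_auc",
]


@dataclass
class HomozygoteModel:
    """Fitted homozygote logistic: logit Pr(major hom) = intercept + slope * beta."""

    intercept: float
    slope: float
    penalized: bool = False  # ridge fallback used (perfect separation)
    n0: int = 0  # minor homozygotes in training
    n1: int = 0  # major homozygotes in training

    def linear_predictor(self, y: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(y, dtype=float)

    def predict_proba(self, y: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(y))


@dataclass
class TransmissionInference:
    """Per-heterozygote transmission probabilities, calls and dosages."""

    prob_group1: np.ndarray  # Pr(resembles major-allele homozygotes)
    hard_call: np.ndarray  # 1{prob > 0.5}
    dosage: np.ndarray  # 2 * prob - 1, in [-1, 1]
    auc: float = np.nan
    model: HomozygoteModel = field(default=None)  # type: ignore[assignment]


def fit_homozygote_model(
    y: np.ndarray, labels: np.ndarray, min_per_class: int = 5
) -> HomozygoteModel:
    """Maximum-likelihood logistic fit of homozygote class on methylation.

    ``labels`` are 0 for minor-allele homozygotes and 1 for major-allele
    homozygotes.  Under perfect separation the MLE diverges; a ridge
    (L2-penalized) fit is substituted and flagged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if y.shape != labels.shape:
        raise InputError("methylation and label vectors must have equal length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 < min_per_class or n1 < min_per_class:
        raise InputError(
            f"both homozygote classes need >= {min_per_class} members (got {n0}, {n1})"
        )
    X = sm.add_constant(y)
    try:
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            fit = sm.Logit(labels, X).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        separated = not np.all(np.isfinite(fit.bse))
        if converged and not separated and np.all(np.abs(fit.params) < 1e4):
            return HomozygoteModel(
                intercept=float(fit.params[0]), slope=float(fit.params[1]), n0=n0, n1=n1
            )
    except Exception:
        pass
    # perfect (or quasi-) separation: weakly penalized fallback.  The ridge
    # acts only as a weakly-informative prior keeping the boundary slope
    # finite; a strong penalty would pull predicted probabilities away from
    # the separation limit.
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
    clf.fit(y.reshape(-1, 1), labels.astype(int))
    return HomozygoteModel(
        intercept=float(clf.intercept_[0]),
        slope=float(clf.coef_[0, 0]),
        penalized=True,
        n0=n0,
        n1=n1,
    )


def predict_transmission(
    model: HomozygoteModel, y_het: np.ndarray, truth: np.ndarray | None = None
) -> TransmissionInference:
    """Apply a homozygote-trained model to heterozygote methylation.

    ``truth``, when available (e.g. duo-resolved transmissions), are 0/1
    labels of true membership in group 1 (the major-homozygote-like
    ordering) and are used only for the AUC.
    """
    prob = model.predict_proba(y_het)
    auc = np.nan
    if truth is not None:
        auc = transmission_auc(prob, truth)
    return TransmissionInference(
        prob_group1=prob,
        hard_call=(prob > 0.5).astype(int),
        dosage=2.0 * prob - 1.0,
        auc=auc,
        model=model,
    )


def transmission_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for ties.

    Returns nan when the truth labels contain a single class.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise InputError("scores and truth must have equal length")
    classes = np.unique(truth)
    if classes.size < 2:
        return np.nan
    return float(roc_auc_score(truth, scores))
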