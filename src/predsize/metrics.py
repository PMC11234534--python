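"""Model fitting and predictive-performance measures.

Logistic models are fitted by maximum likelihood (statsmodels).  The three
performance measures are the calibration slope (coefficient of the
estimated linear predictor in a logistic recalibration model fitted to
validation data), the c-statistic (pairwise concordance with ties scored
0.5, computed in O(n log n) via rank sums) and MAPE (mean absolute
difference between estimated and true event probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "FittedModel",
    "ReplicatePerformance",
    "fit_logistic_mle",
    "calibration_slope",
    "c_statistic",
    "mape",
    "rmsd_cs",
]

_PROB_EPS = 1e-12  # probability clip before logit/log transforms
_SEPARATION_LP = 30.0  # |fitted lp| beyond this flags quasi-separation


@dataclass
class FittedModel:
    """MLE logistic fit with convergence diagnostics.

    ``coef`` holds the intercept first.  ``delta_chi2`` is the
    likelihood-ratio statistic against the intercept-only model.
    """

    coef: np.ndarray
    converged: bool
    separation_flag: bool
    deviance_null: float
    deviance_model: float

    @property
    def delta_chi2(self) -> float:
        return self.deviance_null - self.deviance_model

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.coef[0] + X @ self.coef[1:]


@dataclass
class ReplicatePerformance:
    """Performance of one developed model on validation data."""

    cs: float
    cstat: float
    mape: float
    converged: bool


def _binary_deviance(y: np.ndarray, pi: np.ndarray) -> float:
    pi = np.clip(pi, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-2.0 * np.sum(y * np.log(pi) + (1 - y) * np.log1p(-pi)))


def fit_logistic_mle(X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit a logistic regression by MLE, flagging separation.

    Raises ``ValueError`` if y contains a single class; non-convergence is
    reported through the ``converged`` flag rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome vector contains a single class")
    Xd = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=100)
            coef = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            # Newton blow-up under (quasi-)separation: salvage with a
            # capped-step refit so the caller can inspect and discard.
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200, method="bfgs")
            coef = np.asarray(res.params, dtype=float)
            converged = False
    lp = Xd @ coef
    separation = bool(np.max(np.abs(lp)) > _SEPARATION_LP) or not np.all(
        np.isfinite(coef)
    )
    phi = y.mean()
    dev_null = _binary_deviance(y, np.full_like(y, phi))
    dev_model = _binary_deviance(y, expit(lp))
    return FittedModel(
        coef=coef,
        converged=converged,
        separation_flag=separation,
        deviance_null=dev_null,
        deviance_model=dev_model,
    )


def calibration_slope(lp_hat: np.ndarray, y: np.ndarray) -> float:
    """Slope of the logistic recalibration model logit(pi) = a0 + a1 * lp_hat.

    Values below 1 indicate overfitting of the development model.
    """
    lp_hat = np.asarray(lp_hat, dtype=float)
    if np.ptp(lp_hat) == 0:
        raise ValueError("lp_hat is constant; calibration slope undefined")
    fit = fit_logistic_mle(lp_hat[:, None], y)
    return float(fit.coef[1])


def c_statistic(pi_hat: np.ndarray, y: np.ndarray) -> float:
    """Pairwise concordance probability with ties scored 0.5.

    Equivalent to the Wilcoxon rank-sum form of the area under the ROC
    curve; identical to the all-pairs double loop.
    """
    y = np.asarray(y)
    pi_hat = np.asarray(pi_hat, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(pi_hat)  # midranks give the 0.5 tie weighting
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def mape(pi_hat: np.ndarray, pi_true: np.ndarray) -> float:
    """Mean absolute difference between estimated and true probabilities."""
    pi_hat = np.asarray(pi_hat, dtype=float)
    pi_true = np.asarray(pi_true, dtype=float)
    if pi_hat.shape != pi_true.shape:
        raise ValueError("pi_hat and pi_true must have the same length")
    return float(np.mean(np.abs(pi_hat - pi_true)))


def rmsd_cs(cs_values) -> float:
    """Root mean square distance of calibration slopes from the ideal 1."""
    cs = np.asarray(cs_values, dtype=float)
    if cs.size == 0:
        raise ValueError("cs_values must be non-empty")
    return float(np.sqrt(np.mean((cs - 1.0) ** 2)))
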