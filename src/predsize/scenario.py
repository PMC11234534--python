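"""Calibrating a scenario to anticipated prevalence and c-statistic.

A development scenario is specified by the anticipated outcome prevalence
``phi``, the anticipated c-statistic ``c`` and a predictor structure.  Under
the working assumption that the linear predictor eta = beta0 + beta'x is
normally distributed across the population, the pair (phi, c) pins down the
mean ``mu`` and standard deviation ``sigma`` of eta.  This module solves that
calibration problem by numerical quadrature and root finding, converts the
calibrated distribution into concrete regression coefficients for any
predictor structure, and derives the Cox-Snell R-squared used by the
closed-form sample-size criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "ScenarioSpec",
    "LinearPredictorModel",
    "induced_prevalence",
    "induced_cstatistic",
    "solve_lp_distribution",
    "approx_r2cs",
    "r2cs_from_large_sample",
    "coefficients_from_lp",
    "calibrate_scenario",
]

# Gauss-Hermite rule for integrals of smooth functions against a normal
# density; 128 nodes keeps the truncation error far below the solver
# tolerance of 1e-6.
_GH_NODES = 128
_gh_x, _gh_w = hermgauss(_GH_NODES)

# Fine grid on the standardised linear predictor for the nested 1-D
# evaluation of the concordance double integral.
_U_GRID = np.linspace(-8.5, 8.5, 4097)
_U_PDF = norm.pdf(_U_GRID)
_U_CDF = norm.cdf(_U_GRID)


class SolverError(RuntimeError):
    """Raised when the (mu, sigma) calibration fails to converge."""


@dataclass
class ScenarioSpec:
    """Anticipated design of a model development study.

    Parameters
    ----------
    prevalence : float
        Anticipated outcome prevalence phi, in (0, 1).
    c_statistic : float
        Anticipated c-statistic of the true model, in (0.5, 1).
    n_params : int
        Number of predictor parameters p (excluding the intercept).
    relative_strengths : array-like, optional
        Vector gamma of length p giving the relative strength of each
        predictor; the realised coefficients are beta = f * gamma.  Defaults
        to equal strengths.
    correlation : array-like, optional
        p x p predictor correlation matrix; identity by default.
    predictor_kind : {"continuous", "binary"}
        Continuous predictors are standard normal; binary predictors are
        independent Bernoulli variables.
    binary_prevalences : array-like, optional
        Per-predictor Bernoulli prevalences when ``predictor_kind="binary"``.
        Defaults to an evenly spaced grid on [0.2, 0.7].
    """

    prevalence: float
    c_statistic: float
    n_params: int
    relative_strengths: np.ndarray | None = None
    correlation: np.ndarray | None = None
    predictor_kind: str = "continuous"
    binary_prevalences: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0.5 < self.c_statistic < 1.0:
            raise ValueError(
                f"c_statistic must be in (0.5,1), got {self.c_statistic}"
            )
        p = int(self.n_params)
        if p < 1:
            raise ValueError("n_params must be >= 1")
        self.n_params = p
        if self.relative_strengths is None:
            self.relative_strengths = np.ones(p)
        self.relative_strengths = np.asarray(self.relative_strengths, dtype=float)
        if self.relative_strengths.shape != (p,):
            raise ValueError("relative_strengths must have length n_params")
        if np.any(self.relative_strengths < 0) or not np.any(
            self.relative_strengths > 0
        ):
            raise ValueError("relative_strengths must be >=0 with at least one >0")
        if self.correlation is None:
            self.correlation = np.eye(p)
        self.correlation = np.asarray(self.correlation, dtype=float)
        _check_correlation(self.correlation, p)
        if self.predictor_kind not in ("continuous", "binary"):
            raise ValueError("predictor_kind must be 'continuous' or 'binary'")
        if self.predictor_kind == "binary":
            if self.binary_prevalences is None:
                self.binary_prevalences = np.linspace(0.2, 0.7, p)
            self.binary_prevalences = np.asarray(self.binary_prevalences, dtype=float)
            if self.binary_prevalences.shape != (p,):
                raise ValueError("binary_prevalences must have length n_params")
            if np.any(self.binary_prevalences <= 0) or np.any(
                self.binary_prevalences >= 1
            ):
                raise ValueError("binary_prevalences must lie in (0,1)")

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("relative_strengths", "correlation", "binary_prevalences"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ScenarioSpec":
        d = json.loads(s)
        return cls(**d)


def _check_correlation(R: np.ndarray, p: int) -> None:
    if R.shape != (p, p):
        raise ValueError(f"correlation must be {p}x{p}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")


@dataclass
class LinearPredictorModel:
    """Calibrated normal linear predictor plus realised coefficients.

    ``eta ~ Normal(mu, sigma^2)`` across the population; ``beta = scale_f *
    gamma`` and ``beta0`` reproduce that distribution under the scenario's
    predictor structure.  ``r2cs`` is the Cox-Snell R-squared implied by the
    calibrated distribution.
    """

    mu: float
    sigma: float
    beta0: float
    scale_f: float
    beta: np.ndarray
    r2cs: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma < 0 or self.scale_f < 0:
            raise ValueError("sigma and scale_f must be non-negative")


def _gauss_hermite_mean(f, mu: float, sigma: float) -> float:
    """E[f(eta)] for eta ~ Normal(mu, sigma^2) by Gauss-Hermite quadrature."""
    eta = mu + np.sqrt(2.0) * sigma * _gh_x
    return float(np.dot(_gh_w, f(eta)) / np.sqrt(np.pi))


def induced_prevalence(mu: float, sigma: float) -> float:
    """Marginal event probability E[expit(eta)] under eta ~ N(mu, sigma^2)."""
    if not (np.isfinite(mu) and np.isfinite(sigma)):
        raise ValueError("mu and sigma must be finite")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return float(expit(mu))
    return _gauss_hermite_mean(expit, mu, sigma)


def induced_cstatistic(mu: float, sigma: float) -> float:
    """C-statistic of the true model under a normal linear predictor.

    With eta0, eta1 iid Normal(mu, sigma^2),

        c = P(eta1 > eta0 | y1 = 1, y0 = 0)
          = E[expit(eta1) (1 - expit(eta0)) 1{eta1 > eta0}] / (phi (1 - phi)).

    The double integral is evaluated as two nested 1-D integrals on a fine
    grid of the standardised predictor (the inner integral by cumulative
    Simpson quadrature).
    """
    if not (np.isfinite(mu) and np.isfinite(sigma)):
        raise ValueError("mu and sigma must be finite")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return 0.5  # identical predictions for all subjects; ties score 0.5
    pi_u = expit(mu + sigma * _U_GRID)
    phi = simpson(pi_u * _U_PDF, x=_U_GRID)
    # inner integral H(x) = int_{-inf}^{x} pdf(u) expit(mu + sigma u) du
    H = cumulative_simpson(pi_u * _U_PDF, x=_U_GRID, initial=0.0)
    # outer: int pdf(u1) pi(u1) [ (CDF(u1) - H(u1)) ] du1  over non-events
    outer = simpson(pi_u * _U_PDF * (_U_CDF - H), x=_U_GRID)
    c = outer / (phi * (1.0 - phi))
    return float(min(max(c, 0.5), 1.0))


def solve_lp_distribution(
    prevalence: float,
    c_statistic: float,
    tol: float = 1e-6,
    sigma_max: float = 15.0,
) -> tuple[float, float]:
    """Find (mu, sigma) of the normal linear predictor matching phi and c.

    The system is solved by nesting two monotone 1-D root finds: for each
    candidate sigma, mu is chosen to match the prevalence (the marginal
    event probability is strictly increasing in mu); the induced c-statistic
    is then strictly increasing in sigma, and a bracketing search on sigma
    matches the target c.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    if not 0.5 < c_statistic < 1.0:
        raise ValueError("c_statistic must be in (0.5,1)")
    if tol <= 0:
        raise ValueError("tol must be positive")

    def mu_for(sigma: float) -> float:
        lo, hi = logit(prevalence) - 8 * sigma - 1, logit(prevalence) + 1
        return brentq(
            lambda m: induced_prevalence(m, sigma) - prevalence,
            lo,
            hi,
            xtol=tol * 1e-2,
        )

    def c_resid(sigma: float) -> float:
        return induced_cstatistic(mu_for(sigma), sigma) - c_statistic

    lo, hi = 1e-8, 1.0
    while c_resid(hi) < 0:
        hi *= 2.0
        if hi > sigma_max:
            raise SolverError(
                f"no sigma <= {sigma_max} attains c={c_statistic}; "
                f"residual at sigma={hi / 2:.3g}: {c_resid(hi / 2):.3g}"
            )
    sigma = brentq(c_resid, lo, hi, xtol=tol * 1e-2)
    mu = mu_for(sigma)
    res_p = induced_prevalence(mu, sigma) - prevalence
    res_c = induced_cstatistic(mu, sigma) - c_statistic
    if abs(res_p) > tol or abs(res_c) > tol:
        raise SolverError(
            f"calibration residuals too large: prevalence {res_p:.3g}, "
            f"c-statistic {res_c:.3g}"
        )
    return float(mu), float(sigma)


def _entropy_term(eta: np.ndarray, a: float = 0.0, b: float = 1.0) -> np.ndarray:
    pi = np.clip(expit(a + b * eta), 1e-15, 1.0 - 1e-15)
    return pi * np.log(pi) + (1.0 - pi) * np.log1p(-pi)


def approx_r2cs(
    prevalence: float, c_statistic: float, method: str = "binormal"
) -> float:
    """Cox-Snell R-squared implied by (phi, c) under a normal linear predictor.

    R2_CS = 1 - exp(-2 (lbar_model - lbar_null)) where lbar_model is the
    expected per-observation log-likelihood of the true model,

        lbar_model = E[ pi log pi + (1 - pi) log(1 - pi) ],  pi = expit(eta),

    and lbar_null = phi log phi + (1-phi) log(1-phi).

    ``method="binormal"`` (the standard approximation) assumes the linear
    predictor is normal with unit variance *within* events and non-events,
    giving c = Phi(delta / sqrt(2)) for mean separation delta and a true
    risk that is exactly logistic-linear in the predictor.
    ``method="marginal"`` instead assumes the linear predictor is normal
    marginally, reusing the (mu, sigma) calibration of
    :func:`solve_lp_distribution`; the two agree closely except at very
    high model strength.
    """
    phi = prevalence
    lbar_null = phi * np.log(phi) + (1.0 - phi) * np.log1p(-phi)
    if method == "binormal":
        if not 0.5 < c_statistic < 1.0:
            raise ValueError("c_statistic must be in (0.5,1)")
        delta = np.sqrt(2.0) * norm.ppf(c_statistic)
        a = float(logit(phi) - delta**2 / 2.0)
        lbar_model = (1.0 - phi) * _gauss_hermite_mean(
            lambda e: _entropy_term(e, a, delta), 0.0, 1.0
        ) + phi * _gauss_hermite_mean(
            lambda e: _entropy_term(e, a, delta), delta, 1.0
        )
    elif method == "marginal":
        mu, sigma = solve_lp_distribution(prevalence, c_statistic)
        lbar_model = _gauss_hermite_mean(_entropy_term, mu, sigma)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(1.0 - np.exp(-2.0 * (lbar_model - lbar_null)))


def coefficients_from_lp(
    spec: ScenarioSpec, mu: float, sigma: float
) -> LinearPredictorModel:
    """Realise regression coefficients reproducing eta ~ N(mu, sigma^2).

    For zero-mean continuous predictors with correlation R the scale factor
    solves f^2 gamma' R gamma = sigma^2 and the intercept is mu.  Binary
    predictors are not standardised: the scale solves the variance equation
    with Bernoulli variances and the intercept absorbs the nonzero mean of
    gamma'x.
    """
    gamma = spec.relative_strengths
    if spec.predictor_kind == "continuous":
        quad = float(gamma @ spec.correlation @ gamma)
        mean_shift = 0.0
    else:
        q = spec.binary_prevalences
        quad = float(np.sum(gamma**2 * q * (1.0 - q)))
        mean_shift = float(gamma @ q)
    if quad <= 0:
        raise ValueError("relative_strengths carry no signal (gamma'R gamma = 0)")
    f = sigma / np.sqrt(quad)
    beta = f * gamma
    beta0 = mu - f * mean_shift
    r2 = approx_r2cs(spec.prevalence, spec.c_statistic)
    return LinearPredictorModel(
        mu=float(mu), sigma=float(sigma), beta0=float(beta0),
        scale_f=float(f), beta=beta, r2cs=r2,
    )


def calibrate_scenario(spec: ScenarioSpec, tol: float = 1e-6) -> LinearPredictorModel:
    """Solve the (mu, sigma) calibration and realise coefficients in one step."""
    mu, sigma = solve_lp_distribution(spec.prevalence, spec.c_statistic, tol=tol)
    return coefficients_from_lp(spec, mu, sigma)


def r2cs_from_large_sample(spec: ScenarioSpec, N: int = 1_000_000, seed: int = 0) -> float:
    """Cox-Snell R-squared from a single very large simulated fit.

    Simulates ``N`` observations from the calibrated scenario, fits the
    logistic model by MLE and returns 1 - exp(-LR/N), where LR is the
    likelihood-ratio statistic against the intercept-only model.
    """
    if N < 100_000:
        raise ValueError("N must be at least 1e5 for a stable estimate")
    from .dgm import simulate_dataset
    from .metrics import fit_logistic_mle

    model = calibrate_scenario(spec)
    data = simulate_dataset(model, spec, N, seed=seed)
    fit = fit_logistic_mle(data.X, data.y)
    lr = fit.deviance_null - fit.deviance_model
    return float(1.0 - np.exp(-lr / N))
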