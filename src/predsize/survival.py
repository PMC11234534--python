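"""Time-to-event extension: exponential survival DGM and Cox evaluation.

Survival times follow a proportional-hazards model with constant baseline
hazard, h(t) = h0 exp(eta), so T | eta ~ Exponential(h0 exp(eta)).  Times
are administratively censored at a fixed time point calibrated so that a
prespecified proportion of observations is uncensored.  Model strength is
quantified by Harrell's c-index; the variance of the normal linear
predictor is tuned so the censoring-free concordance matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
import pandas as pd

from .scenario import LinearPredictorModel, ScenarioSpec, _gauss_hermite_mean
from .dgm import _as_seedseq

__all__ = [
    "SurvivalDataset",
    "solve_lp_sigma_for_cindex",
    "simulate_survival",
    "calibrate_censor_time",
    "harrell_cindex",
    "survival_calibration_slope",
    "survival_lp_model",
    "evaluate_survival_performance",
    "fit_cox_mle",
    "censorfree_cindex",
]


@dataclass
class SurvivalDataset:
    """Censored survival data with the underlying truth retained."""

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    lp_true: np.ndarray
    censor_time: float

    @property
    def uncensored_prop(self) -> float:
        return float(np.mean(self.event))


def censorfree_cindex(sigma: float) -> float:
    """Concordance of the true model without censoring.

    For an exponential PH model, a pair with linear predictors (a, b) is
    concordant with probability expit(|a - b|); with eta ~ N(mu, sigma^2)
    the difference is N(0, 2 sigma^2), so the c-index is E[expit(|D|)]
    (independent of mu).
    """
    if sigma == 0:
        return 0.5
    u = np.linspace(0.0, 8.5, 2049)
    d = np.sqrt(2.0) * sigma * u
    # half-normal density of |D| scaled back to the standard grid
    return float(simpson(2.0 * norm.pdf(u) * expit(d), x=u))


def solve_lp_sigma_for_cindex(c_index: float, tol: float = 1e-8) -> float:
    """Standard deviation of the linear predictor matching a target c-index."""
    if not 0.5 < c_index < 1.0:
        raise ValueError("c_index must be in (0.5, 1)")
    hi = 1.0
    while censorfree_cindex(hi) < c_index:
        hi *= 2.0
        if hi > 50:
            raise ValueError(f"c_index={c_index} unattainable")
    return float(brentq(lambda s: censorfree_cindex(s) - c_index, 1e-9, hi, xtol=tol))


def simulate_survival(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    n: int,
    baseline_rate: float,
    censor_time: float,
    seed,
) -> SurvivalDataset:
    """Draw exponential survival data, administratively censored."""
    if baseline_rate <= 0 or censor_time <= 0:
        raise ValueError("baseline_rate and censor_time must be positive")
    ss = _as_seedseq(seed)
    x_ss, t_ss = ss.spawn(2)
    rng_x = np.random.default_rng(x_ss)
    p = spec.n_params
    Z = rng_x.standard_normal((n, p))
    L = np.linalg.cholesky(spec.correlation)
    X = Z @ L.T
    lp = model.beta0 + X @ model.beta
    rate = baseline_rate * np.exp(lp)
    t_raw = np.random.default_rng(t_ss).exponential(size=n) / rate
    event = (t_raw <= censor_time).astype(np.int8)
    time = np.minimum(t_raw, censor_time)
    return SurvivalDataset(
        X=X, time=time, event=event, lp_true=lp, censor_time=float(censor_time)
    )


def calibrate_censor_time(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    baseline_rate: float,
    target_uncensored: float,
    tol: float = 1e-8,
) -> float:
    """Administrative censoring time yielding a target event proportion.

    Solves P(T <= t) = target where the marginal event probability is
    E_eta[1 - exp(-h0 e^eta t)], computed by Gauss-Hermite quadrature.
    ``target_uncensored=1`` returns infinity (no censoring).
    """
    if not 0.0 < target_uncensored <= 1.0:
        raise ValueError("target_uncensored must be in (0, 1]")
    if target_uncensored == 1.0:
        return float("inf")

    def p_event(t: float) -> float:
        return _gauss_hermite_mean(
            lambda eta: -np.expm1(-baseline_rate * np.exp(eta) * t),
            model.mu,
            model.sigma,
        )

    hi = 1.0 / baseline_rate
    while p_event(hi) < target_uncensored:
        hi *= 2.0
    return float(
        brentq(lambda t: p_event(t) - target_uncensored, 1e-300, hi, rtol=tol)
    )


def harrell_cindex(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance under right censoring.

    Comparable pairs are those where the shorter observed time is an
    event; ties in the linear predictor score 0.5.  Higher lp must mean
    shorter survival.
    """
    event = np.asarray(event)
    if event.sum() == 0:
        raise ValueError("no events: no comparable pairs")
    # concordance_index scores higher prediction ~ longer survival
    return float(concordance_index(time, -np.asarray(lp, dtype=float), event))


def survival_calibration_slope(
    lp_hat: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Calibration slope for survival models.

    Coefficient of the estimated linear predictor in a Cox model fitted to
    validation data; 1 is ideal, below 1 indicates overfitting.
    """
    event = np.asarray(event)
    if event.sum() == 0:
        raise ValueError("no events in validation data")
    df = pd.DataFrame(
        {"time": np.asarray(time, dtype=float), "event": event,
         "lp": np.asarray(lp_hat, dtype=float)}
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["lp"])


def r2cs_survival_from_large_sample(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    baseline_rate: float,
    censor_time: float,
    N: int = 40_000,
    seed: int = 0,
) -> float:
    """Cox-Snell R-squared of the survival model from a large simulated fit.

    1 - exp(-LR/N) with LR the partial-likelihood ratio statistic of the
    Cox fit against the null.  Censoring reduces the information per
    subject, so the value depends strongly on the uncensored proportion;
    it feeds the calibration-based sample-size formula for survival
    outcomes.
    """
    d = simulate_survival(model, spec, N, baseline_rate, censor_time, seed)
    cols = {f"x{j + 1}": d.X[:, j] for j in range(spec.n_params)}
    cols["time"] = d.time
    cols["event"] = d.event
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame(cols), duration_col="time", event_col="event")
    lr = float(cph.log_likelihood_ratio_test().test_statistic)
    return float(1.0 - np.exp(-lr / N))


def survival_lp_model(spec: ScenarioSpec, c_index: float) -> LinearPredictorModel:
    """Realise coefficients for a survival scenario with a target c-index.

    The normal linear predictor is centred at zero; its standard deviation
    is tuned so the censoring-free concordance equals ``c_index`` and the
    coefficients are scaled to reproduce that variance under the scenario's
    predictor structure.
    """
    sigma = solve_lp_sigma_for_cindex(c_index)
    gamma = spec.relative_strengths
    quad = float(gamma @ spec.correlation @ gamma)
    if quad <= 0:
        raise ValueError("relative_strengths carry no signal")
    f = sigma / np.sqrt(quad)
    return LinearPredictorModel(
        mu=0.0, sigma=float(sigma), beta0=0.0, scale_f=float(f),
        beta=f * gamma, r2cs=float("nan"),
    )


def evaluate_survival_performance(
    spec: ScenarioSpec,
    n: int,
    c_index: float,
    uncensored: float,
    n_sim: int = 200,
    n_val: int = 25_000,
    baseline_rate: float = 0.1,
    seed: int = 0,
) -> dict:
    """Distribution of the survival calibration slope and c-index at size n.

    Mirrors the binary engine: each replicate fits a Cox model to a
    simulated development sample and scores it on a fresh validation set
    censored at the same calibrated time point.
    """
    model = survival_lp_model(spec, c_index)
    censor_time = calibrate_censor_time(model, spec, baseline_rate, uncensored)
    if not np.isfinite(censor_time):
        censor_time = np.finfo(float).max / 1e10
    cs_vals, ci_vals = [], []
    for i in range(n_sim):
        dev_ss = np.random.SeedSequence(entropy=(seed, i, 0))
        dev = simulate_survival(model, spec, n, baseline_rate, censor_time, dev_ss)
        if dev.event.sum() < spec.n_params + 2:
            continue
        try:
            coef = fit_cox_mle(dev.X, dev.time, dev.event)
        except Exception:
            continue
        val_ss = np.random.SeedSequence(entropy=(seed, i, 1))
        val = simulate_survival(model, spec, n_val, baseline_rate, censor_time, val_ss)
        lp_hat = val.X @ coef
        cs_vals.append(survival_calibration_slope(lp_hat, val.time, val.event))
        ci_vals.append(harrell_cindex(lp_hat, val.time, val.event))
    cs = np.asarray(cs_vals)
    ci = np.asarray(ci_vals)
    return {
        "n": n,
        "n_sim": len(cs_vals),
        "uncensored": uncensored,
        "censor_time": float(censor_time),
        "mean_cs": float(cs.mean()),
        "mcse_cs": float(cs.std(ddof=1) / np.sqrt(len(cs))),
        "mean_cindex": float(ci.mean()),
        "seed": seed,
    }


def fit_cox_mle(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Cox partial-likelihood fit; returns the coefficient vector."""
    p = X.shape[1]
    cols = {f"x{j + 1}": X[:, j] for j in range(p)}
    cols["time"] = np.asarray(time, dtype=float)
    cols["event"] = np.asarray(event)
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame(cols), duration_col="time", event_col="event")
    return cph.params_.to_numpy()
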