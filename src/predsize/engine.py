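"""Monte Carlo evaluation of predictive performance at a given sample size.

For each replicate a development dataset of size n is simulated, a logistic
model is fitted by MLE, and its calibration slope, c-statistic and MAPE are
computed on a fresh large validation dataset.  Summaries include the mean
and Monte Carlo standard error of each measure, the RMSD of the calibration
slope from 1, and the tail probabilities used to judge model stability.

Replicate streams are derived deterministically from (master seed,
replicate index), so results are reproducible and — because datasets grow
by row with n (see :mod:`predsize.dgm`) — evaluations at different sample
sizes share common random numbers, which makes the mean-performance curve
smooth in n during a search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dgm import DEFAULT_N_VAL, simulate_dataset
from .metrics import (
    ReplicatePerformance,
    c_statistic,
    calibration_slope,
    fit_logistic_mle,
    mape,
    rmsd_cs,
)
from .scenario import (
    LinearPredictorModel,
    ScenarioSpec,
    calibrate_scenario,
    induced_cstatistic,
)

__all__ = ["PerformanceDistribution", "evaluate_performance", "mcse"]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 20


def mcse(values) -> float:
    """Monte Carlo standard error: sample SD over sqrt(n_sim)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class PerformanceDistribution:
    """Distribution of validation performance over replicated developments."""

    n: int
    n_sim: int
    n_val: int
    per_replicate: list[ReplicatePerformance]
    mean_cs: float
    sd_cs: float
    mcse_cs: float
    rmsd_cs: float
    mean_mape: float
    mcse_mape: float
    mean_cstat: float
    true_cstat: float
    p_cs_below_08: float
    p_cs_below_09: float
    p_cstat_within_002: float
    seed: int
    n_excluded: int = 0

    @property
    def cs_values(self) -> np.ndarray:
        return np.array([r.cs for r in self.per_replicate])

    @property
    def mape_values(self) -> np.ndarray:
        return np.array([r.mape for r in self.per_replicate])

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n", "n_sim", "n_val", "mean_cs", "sd_cs", "mcse_cs",
                "rmsd_cs", "mean_mape", "mcse_mape", "mean_cstat",
                "true_cstat", "p_cs_below_08", "p_cs_below_09",
                "p_cstat_within_002", "seed", "n_excluded",
            )
        }
        return d


def _one_replicate(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    n: int,
    n_val: int,
    seed: int,
    rep: int,
) -> tuple[ReplicatePerformance, int]:
    """Fit one development replicate and score it on validation data.

    Non-converged or separated fits are discarded and redrawn from a fresh
    substream, so the estimand remains 'models successfully fitted by MLE'.
    Returns the performance record and the number of discarded draws.
    """
    redraws = 0
    for attempt in range(_MAX_REDRAWS):
        dev_ss = np.random.SeedSequence(entropy=(seed, rep, 0, attempt))
        dev = simulate_dataset(model, spec, n, seed=dev_ss)
        if dev.y.min() == dev.y.max():
            redraws += 1
            continue
        fit = fit_logistic_mle(dev.X, dev.y)
        if not fit.converged or fit.separation_flag:
            redraws += 1
            continue
        val_ss = np.random.SeedSequence(entropy=(seed, rep, 1))
        val = simulate_dataset(model, spec, n_val, seed=val_ss)
        lp_hat = fit.linear_predictor(val.X)
        pi_hat = expit(lp_hat)
        perf = ReplicatePerformance(
            cs=calibration_slope(lp_hat, val.y),
            cstat=c_statistic(pi_hat, val.y),
            mape=mape(pi_hat, val.pi_true),
            converged=True,
        )
        return perf, redraws
    raise RuntimeError(
        f"replicate {rep}: {_MAX_REDRAWS} consecutive fits failed; "
        f"n={n} is likely too small for this scenario"
    )


def evaluate_performance(
    spec: ScenarioSpec,
    n: int,
    n_sim: int = 1000,
    n_val: int = DEFAULT_N_VAL,
    seed: int = 0,
    model: LinearPredictorModel | None = None,
) -> PerformanceDistribution:
    """Distribution of CS, c-statistic and MAPE at development size n."""
    if model is None:
        model = calibrate_scenario(spec)
    if n * spec.prevalence < 2 * spec.n_params:
        logger.warning(
            "n*phi = %.1f < 2p = %d: expect unstable fits",
            n * spec.prevalence, 2 * spec.n_params,
        )
    reps: list[ReplicatePerformance] = []
    excluded = 0
    for i in range(n_sim):
        perf, redraws = _one_replicate(model, spec, n, n_val, seed, i)
        excluded += redraws
        reps.append(perf)
    if excluded > 0.01 * n_sim:
        logger.warning(
            "%d of %d development fits were discarded (non-convergence or "
            "separation) and redrawn", excluded, n_sim,
        )
    cs = np.array([r.cs for r in reps])
    mp = np.array([r.mape for r in reps])
    cst = np.array([r.cstat for r in reps])
    true_c = induced_cstatistic(model.mu, model.sigma)
    return PerformanceDistribution(
        n=n,
        n_sim=n_sim,
        n_val=n_val,
        per_replicate=reps,
        mean_cs=float(cs.mean()),
        sd_cs=float(cs.std(ddof=1)),
        mcse_cs=mcse(cs),
        rmsd_cs=rmsd_cs(cs),
        mean_mape=float(mp.mean()),
        mcse_mape=mcse(mp),
        mean_cstat=float(cst.mean()),
        true_cstat=true_c,
        p_cs_below_08=float(np.mean(cs < 0.8)),
        p_cs_below_09=float(np.mean(cs < 0.9)),
        p_cstat_within_002=float(np.mean(np.abs(cst - true_c) <= 0.02)),
        seed=seed,
        n_excluded=excluded,
    )
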