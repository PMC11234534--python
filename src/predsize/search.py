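"""Simulation-based sample-size determination.

Finds the development sample size n at which the expected validation
calibration slope reaches a target S (the mean CS is increasing in n), or
the expected MAPE reaches a target m (decreasing in n).  The search
brackets the solution starting from the corresponding closed-form value,
bisects on a grid of 10 using common random numbers across sample sizes,
and finishes with a secant refinement between the tightest bracketing
evaluations followed by a confirmatory evaluation at the returned n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dgm import DEFAULT_N_VAL
from .engine import PerformanceDistribution, evaluate_performance
from .formulas import epv, round_n, rvs1_n, rvs2_n
from .scenario import LinearPredictorModel, ScenarioSpec, calibrate_scenario

__all__ = ["SampleSizeResult", "find_n_for_cs", "find_n_for_mape"]

logger = logging.getLogger(__name__)


class SearchError(RuntimeError):
    """Raised when the stochastic search cannot establish a valid bracket."""


@dataclass
class SampleSizeResult:
    """Result of a simulation-based sample-size search."""

    criterion: str
    target: float
    n_found: int
    achieved: float
    achieved_mcse: float
    evaluations: list[tuple[int, float, float]]
    seed: int
    epv: float
    n_sim: int
    n_val: int
    bound_hit: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "target": self.target,
            "n": self.n_found,
            "achieved": self.achieved,
            "achieved_mcse": self.achieved_mcse,
            "epv": self.epv,
            "n_sim": self.n_sim,
            "n_val": self.n_val,
            "seed": self.seed,
            "bound_hit": self.bound_hit,
            "message": self.message,
            "evaluations": [list(e) for e in self.evaluations],
        }


def _grid(n: float) -> int:
    return max(10, int(round(n / 10.0)) * 10)


def _search(
    spec: ScenarioSpec,
    model: LinearPredictorModel,
    criterion: str,
    target: float,
    metric: str,
    increasing: bool,
    n_start: int,
    n_sim: int,
    n_val: int,
    seed: int,
    tol: float,
    n_min: int,
    n_max: int = 5_000_000,
) -> SampleSizeResult:
    cache: dict[int, PerformanceDistribution] = {}

    def f(n: int) -> float:
        if n not in cache:
            cache[n] = evaluate_performance(
                spec, n, n_sim=n_sim, n_val=n_val, seed=seed, model=model
            )
            logger.info("evaluated n=%d: %s=%.5f", n, metric, getattr(cache[n], metric))
        return float(getattr(cache[n], metric))

    def short(dist: PerformanceDistribution) -> float:
        # signed distance below target in the direction 'n too small'
        v = float(getattr(dist, metric))
        return (target - v) if increasing else (v - target)

    def deficit(n: int) -> float:
        f(n)
        return short(cache[n])

    # --- establish a bracket [lo, hi] with deficit(lo) > 0 > deficit(hi)
    lo = max(n_min, _grid(n_start / 2))
    hi = min(n_max, _grid(n_start * 4))
    while deficit(lo) <= 0:
        if lo <= n_min:
            dist = cache[lo]
            return _finish(
                criterion, target, lo, dist, cache, spec, seed, n_sim, n_val,
                bound_hit=True,
                message=(
                    f"target already met at the minimum usable size n={lo}; "
                    "the requested target is very weak for this scenario"
                ),
            )
        hi = lo
        lo = max(n_min, _grid(lo / 2))
    while deficit(hi) > 0:
        if hi >= n_max:
            raise SearchError(
                f"target {metric}={target} not reached by n={n_max}"
            )
        lo = hi
        hi = min(n_max, _grid(hi * 2))

    # --- bisection on the 10-grid; common random numbers keep the
    # mean-performance curve effectively monotone across n
    escalated = False
    while hi - lo > 10:
        mid = _grid((lo + hi) / 2)
        if mid in (lo, hi):
            break
        d_mid = deficit(mid)
        f_mid = float(getattr(cache[mid], metric))
        f_lo = float(getattr(cache[lo], metric))
        f_hi = float(getattr(cache[hi], metric))
        band = (min(f_lo, f_hi) - 5 * tol, max(f_lo, f_hi) + 5 * tol)
        if not band[0] <= f_mid <= band[1]:
            # evaluation noisier than the bracket allows: escalate once
            if escalated:
                raise SearchError(
                    "non-monotone evaluations persist after n_sim escalation; "
                    f"trace: {[(n, float(getattr(d, metric))) for n, d in sorted(cache.items())]}"
                )
            logger.warning("noisy evaluation at n=%d; doubling n_sim", mid)
            escalated = True
            n_sim *= 2
            cache.clear()
            if deficit(lo) <= 0 or deficit(hi) > 0:
                raise SearchError("bracket lost after n_sim escalation")
            continue
        if abs(d_mid) <= tol:
            lo_ref, hi_ref = (lo, mid) if d_mid <= 0 else (mid, hi)
            n_star = _interpolate(cache, metric, target, lo_ref, hi_ref)
            return _finish(
                criterion, target, n_star, None, cache, spec, seed, n_sim,
                n_val, model=model,
            )
        if d_mid > 0:
            lo = mid
        else:
            hi = mid

    n_star = _interpolate(cache, metric, target, lo, hi)
    return _finish(
        criterion, target, n_star, None, cache, spec, seed, n_sim, n_val,
        model=model,
    )


def _interpolate(cache, metric: str, target: float, lo: int, hi: int) -> int:
    """Secant step between the tightest bracketing evaluations."""
    f_lo = float(getattr(cache[lo], metric))
    f_hi = float(getattr(cache[hi], metric))
    if f_hi == f_lo:
        n_star = hi
    else:
        n_star = lo + (target - f_lo) / (f_hi - f_lo) * (hi - lo)
        n_star = min(max(n_star, lo), hi)
    return round_n(max(n_star, 10), "up10")


def _finish(
    criterion, target, n_found, dist, cache, spec, seed, n_sim, n_val,
    model=None, bound_hit=False, message="",
) -> SampleSizeResult:
    if dist is None:
        if n_found not in cache:
            cache[n_found] = evaluate_performance(
                spec, n_found, n_sim=n_sim, n_val=n_val, seed=seed, model=model
            )
        dist = cache[n_found]
    metric = "mean_cs" if criterion == "expected_cs" else "mean_mape"
    mcse_attr = "mcse_cs" if criterion == "expected_cs" else "mcse_mape"
    trace = [
        (n, float(getattr(d, metric)), float(getattr(d, mcse_attr)))
        for n, d in sorted(cache.items())
    ]
    return SampleSizeResult(
        criterion=criterion,
        target=target,
        n_found=int(n_found),
        achieved=float(getattr(dist, metric)),
        achieved_mcse=float(getattr(dist, mcse_attr)),
        evaluations=trace,
        seed=seed,
        epv=epv(n_found, spec.prevalence, spec.n_params),
        n_sim=n_sim,
        n_val=n_val,
        bound_hit=bound_hit,
        message=message,
    )


def _n_min(spec: ScenarioSpec) -> int:
    # smallest size at which MLE with p parameters is routinely feasible
    return _grid(max(50, 2 * spec.n_params / min(spec.prevalence, 1 - spec.prevalence)))


def find_n_for_cs(
    spec: ScenarioSpec,
    S_target: float = 0.9,
    n_sim: int = 1000,
    n_val: int = DEFAULT_N_VAL,
    seed: int = 0,
    tol_cs: float = 0.005,
    model: LinearPredictorModel | None = None,
) -> SampleSizeResult:
    """Sample size at which the expected calibration slope equals S_target."""
    if not 0.7 <= S_target < 1.0:
        raise ValueError("S_target must be in [0.7, 1)")
    if not 0.85 <= S_target <= 0.95:
        logger.warning("S_target=%.2f is outside the usual [0.85, 0.95]", S_target)
    if model is None:
        model = calibrate_scenario(spec)
    start = rvs1_n(spec.n_params, S_target, model.r2cs).n_raw
    return _search(
        spec, model, "expected_cs", S_target, "mean_cs", True,
        int(start), n_sim, n_val, seed, tol_cs, _n_min(spec),
    )


def find_n_for_mape(
    spec: ScenarioSpec,
    m_target: float | None = None,
    n_sim: int = 1000,
    n_val: int = DEFAULT_N_VAL,
    seed: int = 0,
    tol_m: float | None = None,
    model: LinearPredictorModel | None = None,
) -> SampleSizeResult:
    """Sample size at which the expected MAPE equals m_target.

    ``m_target`` defaults to prevalence/10, the convention used throughout
    the grid studies.
    """
    if m_target is None:
        m_target = spec.prevalence / 10.0
    if m_target <= 0:
        raise ValueError("m_target must be positive")
    if tol_m is None:
        tol_m = 0.002 * m_target
    if model is None:
        model = calibrate_scenario(spec)
    start = rvs2_n(spec.n_params, spec.prevalence, m_target).n_raw
    return _search(
        spec, model, "expected_mape", m_target, "mean_mape", False,
        int(start), n_sim, n_val, seed, tol_m, _n_min(spec),
    )
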