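"""Closed-form sample-size criteria for model development.

Two criteria are implemented.  The calibration criterion targets an expected
shrinkage (calibration slope) S and is derived from the heuristic shrinkage
factor S = (chi2 - p)/chi2:

    n = p / ((S - 1) log(1 - R2_CS / S)),

where R2_CS is the Cox-Snell R-squared of the anticipated model.  The MAPE
criterion targets an expected mean absolute prediction error m:

    n = exp((-0.508 + 0.259 log(phi) + 0.504 log(p) - log(m)) / 0.544),

a regression fit to large-scale simulation results; it does not involve
model strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class FormulaResult:
    """Outcome of a closed-form sample-size evaluation.

    ``epv`` (events per variable, n*phi/p) is computed from the unrounded
    sample size when the prevalence is known, so that it does not inherit
    rounding artefacts; it is ``nan`` for the calibration criterion when no
    prevalence was supplied.
    """

    criterion: str
    n_raw: float
    n_rounded: int
    epv: float
    inputs: dict

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "n_raw": self.n_raw,
            "n": self.n_rounded,
            "epv": self.epv,
            "inputs": self.inputs,
        }


def round_n(n_raw: float, mode: str = "nearest10") -> int:
    """Round a raw sample size to the 10-grid.

    ``nearest10`` rounds half away from zero (6235.0 -> 6240); ``up10``
    always rounds upward, the convention for user-facing recommendations.
    """
    if n_raw <= 0:
        raise ValueError("n_raw must be positive")
    if mode == "nearest10":
        return int(math.floor(n_raw / 10.0 + 0.5) * 10)
    if mode == "up10":
        return int(math.ceil(n_raw / 10.0) * 10)
    raise ValueError(f"unknown rounding mode {mode!r}")


def epv(n: float, prevalence: float, p: int) -> float:
    """Events per variable: n * phi / p."""
    if n <= 0 or p <= 0 or not 0 < prevalence < 1:
        raise ValueError("n, p must be positive and prevalence in (0,1)")
    return n * prevalence / p


def heuristic_shrinkage(delta_chi2: float, p: int) -> float:
    """Heuristic shrinkage factor (chi2 - p) / chi2.

    ``delta_chi2`` is the likelihood-ratio (deviance) statistic of the
    fitted model against the null and ``p`` the number of predictor
    parameters.  Values below 1 quantify expected overfitting.
    """
    if delta_chi2 <= 0:
        raise ValueError("delta_chi2 must be positive")
    return (delta_chi2 - p) / delta_chi2


def rvs1_n(
    p: int,
    S_target: float,
    r2cs: float,
    prevalence: float | None = None,
    rounding: str = "nearest10",
) -> FormulaResult:
    """Calibration-based sample size for a target expected shrinkage S."""
    if not 0.0 < S_target < 1.0:
        raise ValueError("S_target must be in (0,1)")
    if not 0.0 < r2cs < S_target:
        raise ValueError(
            f"need 0 < r2cs < S_target for a valid log argument; "
            f"got r2cs={r2cs}, S_target={S_target}"
        )
    n_raw = p / ((S_target - 1.0) * math.log(1.0 - r2cs / S_target))
    n_round = round_n(n_raw, rounding)
    e = epv(n_raw, prevalence, p) if prevalence is not None else float("nan")
    return FormulaResult(
        criterion="rvs1_calibration",
        n_raw=n_raw,
        n_rounded=n_round,
        epv=e,
        inputs={"p": p, "S": S_target, "r2cs": r2cs, "prevalence": prevalence},
    )


def rvs2_n(
    p: int,
    prevalence: float,
    m_target: float,
    rounding: str = "nearest10",
) -> FormulaResult:
    """MAPE-based sample size for a target expected MAPE m."""
    if m_target <= 0:
        raise ValueError("m_target must be positive")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    n_raw = math.exp(
        (
            -0.508
            + 0.259 * math.log(prevalence)
            + 0.504 * math.log(p)
            - math.log(m_target)
        )
        / 0.544
    )
    return FormulaResult(
        criterion="rvs2_mape",
        n_raw=n_raw,
        n_rounded=round_n(n_raw, rounding),
        epv=epv(n_raw, prevalence, p),
        inputs={"p": p, "m": m_target, "prevalence": prevalence},
    )
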