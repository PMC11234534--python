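"""Data-generating mechanisms for development and validation datasets.

Predictors are either multivariate normal with zero mean, unit variance and
a block-exchangeable correlation structure, or independent Bernoulli
variables; binary outcomes follow Bernoulli(expit(beta0 + beta'x)).

Random streams: every dataset is drawn from a ``numpy.random.SeedSequence``.
The predictor matrix and the outcome uniforms use separately spawned child
streams and are filled row-wise, so a dataset of size n1 is exactly the
first n1 rows of the dataset of size n2 > n1 drawn from the same seed.  The
simulation engine exploits this coupling (common random numbers) when
comparing sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .scenario import LinearPredictorModel, ScenarioSpec, _check_correlation

__all__ = [
    "SimulatedDataset",
    "make_correlation_matrix",
    "simulate_dataset",
    "simulate_validation",
    "main_study_spec",
    "equal_strength_spec",
    "DEFAULT_N_VAL",
    "STUDY_N_VAL",
]

# engine default validation size; the full-replication convention is 100k
DEFAULT_N_VAL = 25_000
STUDY_N_VAL = 100_000


@dataclass
class SimulatedDataset:
    """Predictors, binary outcomes and the underlying truth."""

    X: np.ndarray
    y: np.ndarray
    pi_true: np.ndarray
    lp_true: np.ndarray


def make_correlation_matrix(
    n_true: int, n_noise: int, r_tt: float, r_nn: float, r_tn: float
) -> np.ndarray:
    """Block-exchangeable correlation matrix for true and noise predictors.

    Correlation is ``r_tt`` within the true block, ``r_nn`` within the noise
    block and ``r_tn`` across blocks, with unit diagonal.  Raises if the
    combination is not positive semi-definite.
    """
    p = n_true + n_noise
    R = np.empty((p, p))
    R[:n_true, :n_true] = r_tt
    R[n_true:, n_true:] = r_nn
    R[:n_true, n_true:] = r_tn
    R[n_true:, :n_true] = r_tn
    np.fill_diagonal(R, 1.0)
    _check_correlation(R, p)
    return R


def main_study_spec(prevalence: float, c_statistic: float) -> ScenarioSpec:
    """The 12-predictor grid-study design: 5 true + 7 noise predictors.

    Relative strengths (0.4, 0.2, 0.2, 0.1, 0.1) for the true predictors,
    zero for noise; pairwise correlation 0.1 within the true block, 0.05
    within the noise block, 0 across blocks.
    """
    gamma = np.array([0.4, 0.2, 0.2, 0.1, 0.1] + [0.0] * 7)
    R = make_correlation_matrix(5, 7, 0.1, 0.05, 0.0)
    return ScenarioSpec(
        prevalence=prevalence,
        c_statistic=c_statistic,
        n_params=12,
        relative_strengths=gamma,
        correlation=R,
    )


def equal_strength_spec(
    prevalence: float, c_statistic: float, n_params: int
) -> ScenarioSpec:
    """Independent predictors of equal strength (the worked-example design)."""
    return ScenarioSpec(
        prevalence=prevalence, c_statistic=c_statistic, n_params=n_params
    )


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_dataset(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    n: int,
    seed,
) -> SimulatedDataset:
    """Draw a development dataset of size n from the calibrated mechanism."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = _as_seedseq(seed)
    x_ss, y_ss = ss.spawn(2)
    rng_x = np.random.default_rng(x_ss)
    p = spec.n_params
    if spec.predictor_kind == "continuous":
        Z = rng_x.standard_normal((n, p))
        L = np.linalg.cholesky(spec.correlation)
        X = Z @ L.T
    else:
        U = rng_x.random((n, p))
        X = (U < spec.binary_prevalences).astype(float)
    lp = model.beta0 + X @ model.beta
    pi = expit(lp)
    u = np.random.default_rng(y_ss).random(n)
    y = (u < pi).astype(np.int8)
    return SimulatedDataset(X=X, y=y, pi_true=pi, lp_true=lp)


def simulate_validation(
    model: LinearPredictorModel,
    spec: ScenarioSpec,
    n_val: int = DEFAULT_N_VAL,
    seed=None,
) -> SimulatedDataset:
    """Draw a large validation dataset; same mechanism, independent stream."""
    return simulate_dataset(model, spec, n_val, seed)
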