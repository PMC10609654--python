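"""Finite-population generator for the simulation study.

The super-population model produces seven variables per unit:

* ``X1`` — three-level categorical drawn from a multinomial with
  probabilities ``x1_probs`` (defaults 0.2/0.3/0.5).
* Latent ``(Z2..Z6)`` — multivariate normal given ``X1`` with mean vector
  ``(X1, X1+3, X1/3, X1+2, 2*X1-3)`` and an equicorrelated covariance
  (unit diagonal, off-diagonal 0.5).
* ``X2 = Z2``, ``X3 = Z3``, ``X7 = Z6`` — continuous.
* ``X4 = 1{Z4 >= 0.5}`` — binary.
* ``X5`` — ordinal with levels 1/2/3 cut from ``Z5`` at 3 and 5
  (half-open intervals, so the levels are exhaustive and disjoint).
* ``X6 ~ Bernoulli(expit(X1 - g(X2) - X3 + X4 + 2*X5))`` — binary, where
  ``g`` is selected by ``x6_x2_term`` (``x2_squared`` by default; see
  docs/methods.md for why the alternatives are exposed).

Because every discrete variable is a deterministic threshold of a Gaussian
latent, the population means and level proportions have closed forms; these
are exposed through :func:`population_moments` and used as analytic oracles
in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .schema import Schema, VariableSchema

#: latent mean rules: per-latent affine function of X1, as (slope, intercept)
DEFAULT_LATENT_MEAN_RULES = (
    (1.0, 0.0),      # Z2: X1
    (1.0, 3.0),      # Z3: X1 + 3
    (1.0 / 3.0, 0.0),  # Z4: X1/3
    (1.0, 2.0),      # Z5: X1 + 2
    (2.0, -3.0),     # Z6: 2*X1 - 3
)

X6_X2_TERMS = ("x2_squared", "two_x2", "half_x2")


def default_schema() -> Schema:
    return {
        "X1": VariableSchema("categorical", (1, 2, 3)),
        "X2": VariableSchema("continuous"),
        "X3": VariableSchema("continuous"),
        "X4": VariableSchema("binary"),
        "X5": VariableSchema("categorical", (1, 2, 3)),
        "X6": VariableSchema("binary"),
        "X7": VariableSchema("continuous"),
    }


COVARIATES = ("X1", "X2", "X3")
OUTCOMES = ("X4", "X5", "X6", "X7")


def _equicorrelated(dim: int, diag: float, offdiag: float) -> np.ndarray:
    cov = np.full((dim, dim), offdiag, dtype=float)
    np.fill_diagonal(cov, diag)
    return cov


@dataclass(frozen=True)
class SuperPopulationConfig:
    """Parameters of the generative super-population model.

    ``latent_mean_rules`` holds one (slope, intercept) pair per latent,
    giving that latent's conditional mean ``slope * X1 + intercept``.
    """

    N: int = 10_000
    x1_probs: tuple = (0.2, 0.3, 0.5)
    latent_mean_rules: tuple = DEFAULT_LATENT_MEAN_RULES
    latent_cov: np.ndarray = field(
        default_factory=lambda: _equicorrelated(5, 1.0, 0.5)
    )
    x4_threshold: float = 0.5
    x5_cuts: tuple = (3.0, 5.0)
    x6_coefs: tuple = (1.0, -1.0, -1.0, 1.0, 2.0)  # on (X1, g(X2), X3, X4, X5)
    x6_x2_term: str = "x2_squared"
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.x1_probs, dtype=float)
        if probs.ndim != 1 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("x1_probs must be a nonnegative vector summing to 1")
        if self.N < 1:
            raise ValueError("population size N must be positive")
        cov = np.asarray(self.latent_cov, dtype=float)
        if cov.shape != (len(self.latent_mean_rules),) * 2:
            raise ValueError("latent_cov shape does not match the latent count")
        if not np.allclose(cov, cov.T):
            raise ValueError("latent_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise ValueError(
                f"latent_cov must be positive definite (min eigenvalue {eigvals.min():.3g})"
            )
        if not self.x5_cuts[0] < self.x5_cuts[1]:
            raise ValueError("x5_cuts must be strictly increasing")
        if self.x6_x2_term not in X6_X2_TERMS:
            raise ValueError(f"x6_x2_term must be one of {X6_X2_TERMS}")

    @property
    def x1_levels(self) -> np.ndarray:
        return np.arange(1, len(np.asarray(self.x1_probs)) + 1)


@dataclass(frozen=True)
class FinitePopulation:
    """A realized finite population: an N-row table plus its schema."""

    values: pd.DataFrame
    schema: Schema
    seed_used: int | None = None

    @property
    def N(self) -> int:
        return len(self.values)

    def mean(self, variable: str, level=None) -> float:
        """Population mean, or level proportion for a discrete variable."""
        col = self.values[variable]
        if level is not None:
            return float((col == level).mean())
        return float(col.mean())


def _x2_term(x2: np.ndarray, tag: str) -> np.ndarray:
    if tag == "x2_squared":
        return x2**2
    if tag == "two_x2":
        return 2.0 * x2
    return 0.5 * x2


def generate_population(
    config: SuperPopulationConfig, rng: np.random.Generator | int | None = None
) -> FinitePopulation:
    """Draw one finite population of size ``config.N`` from the model."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    N = config.N
    probs = np.asarray(config.x1_probs, dtype=float)
    x1 = rng.choice(config.x1_levels, size=N, p=probs)

    slopes = np.array([r[0] for r in config.latent_mean_rules])
    intercepts = np.array([r[1] for r in config.latent_mean_rules])
    mean = x1[:, None] * slopes + intercepts
    chol = np.linalg.cholesky(np.asarray(config.latent_cov, dtype=float))
    z = mean + rng.standard_normal((N, len(slopes))) @ chol.T

    x2, x3, x7 = z[:, 0], z[:, 1], z[:, 4]
    x4 = (z[:, 2] >= config.x4_threshold).astype(np.int64)
    lo, hi = config.x5_cuts
    x5 = np.where(z[:, 3] <= lo, 1, np.where(z[:, 3] <= hi, 2, 3)).astype(np.int64)

    b = config.x6_coefs
    eta = (
        b[0] * x1
        + b[1] * _x2_term(x2, config.x6_x2_term)
        + b[2] * x3
        + b[3] * x4
        + b[4] * x5
    )
    x6 = (rng.random(N) < expit(eta)).astype(np.int64)

    values = pd.DataFrame(
        {"X1": x1.astype(np.int64), "X2": x2, "X3": x3, "X4": x4,
         "X5": x5, "X6": x6, "X7": x7}
    )
    return FinitePopulation(values=values, schema=default_schema(), seed_used=config.seed)


def population_moments(config: SuperPopulationConfig) -> dict:
    """Closed-form super-population means and level proportions.

    All discrete variables except X6 are Gaussian thresholds, so their level
    probabilities are mixtures of normal CDF values over the X1 categories.
    X6 has no closed form (a logistic of correlated Gaussians); it is omitted.
    """
    probs = np.asarray(config.x1_probs, dtype=float)
    levels = config.x1_levels.astype(float)
    e_x1 = float(probs @ levels)
    slopes = [r[0] for r in config.latent_mean_rules]
    intercepts = [r[1] for r in config.latent_mean_rules]
    sd = np.sqrt(np.diag(np.asarray(config.latent_cov, dtype=float)))

    def mix_cdf(threshold, idx):
        # P(Z_idx <= threshold) marginally over X1
        mu = slopes[idx] * levels + intercepts[idx]
        return float(probs @ ndtr((threshold - mu) / sd[idx]))

    p_x4 = 1.0 - mix_cdf(config.x4_threshold, 2)
    p_x5_1 = mix_cdf(config.x5_cuts[0], 3)
    p_x5_le2 = mix_cdf(config.x5_cuts[1], 3)

    out = {
        "X2": slopes[0] * e_x1 + intercepts[0],
        "X3": slopes[1] * e_x1 + intercepts[1],
        "X7": slopes[4] * e_x1 + intercepts[4],
        ("X1", 1): float(probs[0]),
        ("X1", 2): float(probs[1]) if len(probs) > 1 else 0.0,
        ("X4", 1): p_x4,
        ("X5", 1): p_x5_1,
        ("X5", 2): p_x5_le2 - p_x5_1,
        ("X5", 3): 1.0 - p_x5_le2,
    }
    return out
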