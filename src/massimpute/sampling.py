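"""Probability and nonprobability sampling designs.

Two designs are provided:

* :func:`draw_srswor` — simple random sampling without replacement with the
  usual design weights ``N/n`` (the probability sample, which observes
  covariates only).
* :func:`draw_poisson` — Poisson sampling with unit-level inclusion
  probabilities ``expit(alpha + beta' x)`` driven by the covariates, the
  informative selection mechanism behind the nonprobability sample.  The
  intercept ``alpha`` is calibrated by :func:`calibrate_selection` so the
  inclusion probabilities sum to a target expected sample size.

Nonprobability samples carry unit weights (they are analysed unweighted
downstream, matching naive practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .population import COVARIATES, FinitePopulation
from .schema import Schema


@dataclass
class SurveySample:
    """A drawn sample: observed sub-table, unit ids and design weights."""

    unit_ids: np.ndarray
    weights: np.ndarray
    observed_columns: tuple
    data: pd.DataFrame
    schema: Schema

    def __post_init__(self) -> None:
        if np.any(self.weights <= 0):
            raise ValueError("design weights must be strictly positive")
        missing = set(self.observed_columns) - set(self.schema)
        if missing:
            raise ValueError(f"observed columns not in schema: {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_hat(self) -> float:
        """Estimated population size, the sum of design weights."""
        return float(self.weights.sum())


@dataclass(frozen=True)
class SelectionModel:
    """Calibrated logistic selection model pi_i = expit(alpha + coefs' x_i)."""

    coefs: tuple
    intercept: float
    target_expected_n: float

    def inclusion_probs(self, pop: FinitePopulation) -> np.ndarray:
        x = pop.values[list(COVARIATES)].to_numpy(dtype=float)
        return expit(self.intercept + x @ np.asarray(self.coefs, dtype=float))


def draw_srswor(
    pop: FinitePopulation, n: int, rng: np.random.Generator | int | None = None
) -> SurveySample:
    """Simple random sample without replacement; weights N/n; covariates only."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not 0 < n <= pop.N:
        raise ValueError(f"sample size {n} not in (0, N={pop.N}]")
    ids = rng.choice(pop.N, size=n, replace=False)
    data = pop.values.iloc[ids][list(COVARIATES)].reset_index(drop=True)
    return SurveySample(
        unit_ids=ids,
        weights=np.full(n, pop.N / n),
        observed_columns=COVARIATES,
        data=data,
        schema=pop.schema,
    )


def calibrate_selection(
    pop: FinitePopulation,
    coefs: tuple = (0.6, 0.3, 0.1),
    target_expected_n: float = 500.0,
    tol: float = 1e-6,
) -> SelectionModel:
    """Solve the intercept so that the inclusion probabilities sum to target.

    The map ``alpha -> sum_i expit(alpha + beta' x_i)`` is strictly increasing
    from 0 to N, so a root exists and is unique whenever
    ``0 < target_expected_n < N``.
    """
    if not 0 < target_expected_n < pop.N:
        raise ValueError("target expected size must lie strictly between 0 and N")
    x = pop.values[list(COVARIATES)].to_numpy(dtype=float)
    eta = x @ np.asarray(coefs, dtype=float)

    def total(alpha: float) -> float:
        return float(expit(alpha + eta).sum() - target_expected_n)

    # bracket around the equal-probability solution, expanding as needed
    center = float(logit(target_expected_n / pop.N) - eta.mean())
    lo, hi = center - 1.0, center + 1.0
    for _ in range(60):
        if total(lo) < 0 < total(hi):
            break
        lo -= 2.0
        hi += 2.0
    else:
        raise RuntimeError(
            f"no sign change for the calibration root in [{lo:.2f}, {hi:.2f}]"
        )
    alpha = brentq(total, lo, hi, xtol=1e-12)
    model = SelectionModel(tuple(coefs), float(alpha), float(target_expected_n))
    achieved = model.inclusion_probs(pop).sum()
    if abs(achieved - target_expected_n) > max(tol, 1e-6 * target_expected_n):
        raise RuntimeError(
            f"calibration failed: sum(pi)={achieved:.6f} vs target {target_expected_n}"
        )
    return model


def draw_poisson(
    pop: FinitePopulation,
    model: SelectionModel,
    rng: np.random.Generator | int | None = None,
) -> SurveySample:
    """Poisson sample: independent Bernoulli(pi_i) inclusion, random size.

    All seven variables are observed; weights are recorded as 1 because the
    nonprobability sample is analysed unweighted.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pi = model.inclusion_probs(pop)
    included = rng.random(pop.N) < pi
    ids = np.flatnonzero(included)
    data = pop.values.iloc[ids].reset_index(drop=True)
    return SurveySample(
        unit_ids=ids,
        weights=np.ones(len(ids)),
        observed_columns=tuple(pop.schema),
        data=data,
        schema=pop.schema,
    )
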