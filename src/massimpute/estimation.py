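"""Survey-weighted estimation, bias metrics and the Rao-Scott comparison.

The mass-imputed estimator of a population mean theta_N = N^-1 sum_i Y_i is

    theta_hat = N_hat^-1 * sum_{i in S_A} w_i * Y_i*,   N_hat = sum w_i,

computed per completed dataset and averaged over the m imputations.  For a
categorical variable the estimand is a level proportion (Y replaced by the
level indicator).  Monte Carlo bias is the average of (estimate - truth)
over simulation replicates.

The Rao-Scott comparison contrasts a weighted and an unweighted categorical
distribution with a Pearson chi-square corrected by a first-order design
effect (Kish's approximation n * sum(w^2) / (sum w)^2); with equal weights
it reduces exactly to the classical Pearson test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .fcs import MassImputedSample
from .population import FinitePopulation
from .sampling import SurveySample


@dataclass(frozen=True)
class EstimateResult:
    variable: str
    level: object  # None for a mean, the level for a proportion
    theta_hat: float
    per_imputation_estimates: tuple
    n_hat: float
    method: str

    def __float__(self) -> float:
        return self.theta_hat


def _indicator(values: np.ndarray, level) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if level is None:
        return v
    return (np.asarray(values) == level).astype(float)


def _check_estimand(schema, variable, level) -> None:
    if variable not in schema:
        raise KeyError(f"unknown variable {variable!r}")
    if level is not None:
        levels = schema[variable].level_tuple()
        if schema[variable].kind == "continuous" or level not in levels:
            raise KeyError(f"level {level!r} not valid for variable {variable!r}")


def mass_estimate(mis: MassImputedSample, variable: str, level=None) -> EstimateResult:
    """Survey-weighted mass-imputed mean (or level proportion)."""
    _check_estimand(mis.base.schema, variable, level)
    w = mis.base.weights
    n_hat = float(w.sum())
    per_imp = tuple(
        float(w @ _indicator(comp[variable].to_numpy(), level) / n_hat)
        for comp in mis.completions
    )
    return EstimateResult(
        variable=variable,
        level=level,
        theta_hat=float(np.mean(per_imp)),
        per_imputation_estimates=per_imp,
        n_hat=n_hat,
        method=mis.spec.label,
    )


def weighted_estimate(sample: SurveySample, variable: str, level=None) -> EstimateResult:
    """Design-weighted mean of an observed variable (e.g. SRSWOR covariates)."""
    _check_estimand(sample.schema, variable, level)
    w = sample.weights
    n_hat = float(w.sum())
    est = float(w @ _indicator(sample.data[variable].to_numpy(), level) / n_hat)
    return EstimateResult(variable, level, est, (est,), n_hat, "weighted")


def naive_estimate(sB: SurveySample, variable: str, level=None) -> EstimateResult:
    """Unweighted mean / level proportion over the nonprobability sample."""
    _check_estimand(sB.schema, variable, level)
    est = float(_indicator(sB.data[variable].to_numpy(), level).mean())
    return EstimateResult(variable, level, est, (est,), float(sB.n), "naive")


def population_truth(pop: FinitePopulation, variable: str, level=None) -> float:
    _check_estimand(pop.schema, variable, level)
    return pop.mean(variable, level)


def bias(estimate, truth: float) -> float:
    """Signed error estimate - truth (accepts EstimateResult or a number)."""
    return float(estimate) - float(truth)


@dataclass(frozen=True)
class RaoScottResult:
    statistic: float
    df: int
    p_value: float
    design_effect: float
    table: pd.DataFrame
    dropped_levels: tuple = ()


def rao_scott_compare(
    weighted: SurveySample, unweighted: SurveySample, variable: str
) -> RaoScottResult:
    """Compare a weighted vs an unweighted categorical distribution.

    Builds the side-by-side frequency table, computes a two-sample Pearson
    chi-square with the weighted sample entered at its Kish effective size,
    and divides by the weighted sample's design effect (first-order
    correction).
    """
    for s in (weighted, unweighted):
        if not s.schema[variable].is_discrete:
            raise ValueError(f"{variable!r} must be categorical in both samples")
    levels = list(weighted.schema[variable].level_tuple())
    w = weighted.weights
    vw = weighted.data[variable].to_numpy()
    vu = unweighted.data[variable].to_numpy()

    kept, dropped = [], []
    for lev in levels:
        if np.any(vw == lev) or np.any(vu == lev):
            kept.append(lev)
        else:
            dropped.append(lev)
    if len(kept) < 2:
        raise ValueError(f"{variable!r} has fewer than 2 observed levels")

    p_w = np.array([w[vw == lev].sum() for lev in kept]) / w.sum()
    counts_u = np.array([(vu == lev).sum() for lev in kept], dtype=float)
    p_u = counts_u / counts_u.sum()

    n_w = len(vw)
    deff = n_w * float((w**2).sum()) / float(w.sum()) ** 2
    counts_w = n_w * p_w

    # two-sample Pearson chi-square on the 2 x C table of counts
    obs = np.vstack([counts_w, counts_u])
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    pearson = float(contrib.sum())
    statistic = pearson / deff
    df = len(kept) - 1
    p_value = float(chi2.sf(statistic, df)) if statistic > 0 else 1.0

    table = pd.DataFrame(
        {
            "level": kept,
            "weighted_pct": 100 * p_w,
            "unweighted_count": counts_u.astype(int),
            "unweighted_pct": 100 * p_u,
        }
    )
    return RaoScottResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        design_effect=deff,
        table=table,
        dropped_levels=tuple(dropped),
    )
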