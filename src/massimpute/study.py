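"""Monte Carlo study: repeated population / sample / imputation cycles.

Each replicate generates a fresh finite population, draws the probability
sample (SRSWOR, n_A) and the nonprobability sample (calibrated Poisson
selection, expected size E(n_B)), runs every configured imputer, and records
for each estimand the population truth, the design-weighted probability-
sample estimate (covariates only), the naive unweighted nonprobability
estimate, and every mass-imputed estimate.  Aggregation over replicates
yields mean estimate, Monte Carlo bias and Monte Carlo variance per
method x estimand — the layout of the study's two summary tables.

Replicates are deterministic given (root seed, replicate index): each
replicate derives its own child random streams from a SeedSequence keyed on
that pair, so results do not depend on execution order and a study can be
reproduced replicate-by-replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    mass_estimate,
    naive_estimate,
    population_truth,
    weighted_estimate,
)
from .fcs import ImputerSpec, mass_impute_fcs
from .latent import mass_impute_latent
from .population import SuperPopulationConfig, generate_population
from .sampling import calibrate_selection, draw_poisson, draw_srswor

#: estimands of the covariate-comparison table (variable, level)
COVARIATE_ESTIMANDS = (("X1", 1), ("X1", 2), ("X2", None), ("X3", None))
#: estimands of the bias-comparison table
OUTCOME_ESTIMANDS = (("X4", None), ("X5", 1), ("X5", 2), ("X6", None), ("X7", None))


def default_imputers(m: int = 10, iterations: int = 5) -> tuple:
    return (
        ImputerSpec(method="pmm", m=m, iterations=iterations),
        ImputerSpec(method="cart", m=m, iterations=iterations),
        ImputerSpec(method="rf", m=m, iterations=iterations),
        ImputerSpec(method="latent_joint", m=m),
    )


@dataclass(frozen=True)
class StudyConfig:
    M: int = 200
    population: SuperPopulationConfig = field(default_factory=SuperPopulationConfig)
    n_A: int = 500
    target_n_B: float = 500.0
    selection_coefs: tuple = (0.6, 0.3, 0.1)
    imputers: tuple = field(default_factory=default_imputers)
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("replicate count M must be >= 1")


@dataclass
class MCResultTable:
    """Aggregated study results plus run metadata."""

    results: pd.DataFrame  # variable, level, method, mean_estimate, mc_bias, mc_variance
    M: int
    seed: int
    config: StudyConfig

    def table1(self) -> pd.DataFrame:
        """Population vs probability-sample vs nonprobability-sample means."""
        wide = self.results.pivot_table(
            index=["variable", "level"],
            columns="method",
            values="mean_estimate",
            dropna=False,
        )
        cols = [c for c in ("population", "probability", "nonprobability") if c in wide]
        return wide[cols].reset_index()

    def table2(self) -> pd.DataFrame:
        """Mean estimate and Monte Carlo bias per imputation method."""
        skip = {"population", "probability", "nonprobability"}
        mask = ~self.results["method"].isin(skip) & self.results.apply(
            lambda r: (r["variable"], None if pd.isna(r["level"]) else int(r["level"]))
            in OUTCOME_ESTIMANDS,
            axis=1,
        )
        out = self.results[mask][
            ["variable", "level", "method", "mean_estimate", "mc_bias", "mc_variance"]
        ]
        return out.reset_index(drop=True)


def _impute(sA, sB, spec: ImputerSpec, rng: np.random.Generator):
    if spec.method == "latent_joint":
        return mass_impute_latent(sA, sB, spec, rng=rng)
    return mass_impute_fcs(sA, sB, spec, rng=rng)


def run_replicate(config: StudyConfig, index: int) -> pd.DataFrame:
    """One full simulation replicate; deterministic given (seed, index)."""
    ss = np.random.SeedSequence((config.seed, index))
    children = ss.spawn(3 + len(config.imputers))
    rng_pop, rng_a, rng_b = (np.random.default_rng(c) for c in children[:3])

    pop = generate_population(config.population, rng_pop)
    sA = draw_srswor(pop, config.n_A, rng_a)
    model = calibrate_selection(pop, config.selection_coefs, config.target_n_B)
    sB = draw_poisson(pop, model, rng_b)

    rows = []

    def add(method, variable, level, estimate, truth):
        rows.append((index, variable, level, method, float(estimate), truth))

    for variable, level in COVARIATE_ESTIMANDS + OUTCOME_ESTIMANDS:
        truth = population_truth(pop, variable, level)
        add("population", variable, level, truth, truth)
        if variable in sA.observed_columns:
            add("probability", variable, level, weighted_estimate(sA, variable, level), truth)
        add("nonprobability", variable, level, naive_estimate(sB, variable, level), truth)

    for spec, child in zip(config.imputers, children[3:]):
        mis = _impute(sA, sB, spec, np.random.default_rng(child))
        for variable, level in OUTCOME_ESTIMANDS:
            truth = population_truth(pop, variable, level)
            add(spec.label, variable, level, mass_estimate(mis, variable, level), truth)

    return pd.DataFrame(
        rows, columns=["replicate", "variable", "level", "method", "estimate", "truth"]
    )


def aggregate(replicates: list, config: StudyConfig) -> MCResultTable:
    """Mean estimate, Monte Carlo bias and variance per method x estimand."""
    df = pd.concat(replicates, ignore_index=True)
    df["error"] = df["estimate"] - df["truth"]
    grouped = (
        df.groupby(["variable", "level", "method"], dropna=False)
        .agg(
            mean_estimate=("estimate", "mean"),
            mc_bias=("error", "mean"),
            mc_variance=("estimate", "var"),
            n_replicates=("estimate", "size"),
        )
        .reset_index()
    )
    grouped["mc_variance"] = grouped["mc_variance"].fillna(0.0)
    M = int(df["replicate"].nunique())
    return MCResultTable(results=grouped, M=M, seed=config.seed, config=config)


def run_study(config: StudyConfig, progress: bool = False) -> MCResultTable:
    """Run all M replicates (optionally in parallel) and aggregate."""
    indices = range(config.M)
    if config.workers > 1:
        from joblib import Parallel, delayed

        reps = Parallel(n_jobs=config.workers)(
            delayed(run_replicate)(config, i) for i in indices
        )
    else:
        reps = []
        for i in indices:
            reps.append(run_replicate(config, i))
            if progress and (i + 1) % 10 == 0:
                print(f"replicate {i + 1}/{config.M}", flush=True)
    return aggregate(list(reps), config)
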