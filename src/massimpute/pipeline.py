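"""File-based integration pipeline for user-supplied survey files.

Runs the whole data-integration workflow on two delimited files: a
probability sample (shared covariates + design weights, e.g. a BRFSS-style
weighted survey) and a nonprobability sample (shared covariates + outcome
variables, e.g. a convenience survey).  The variable mapping declares which
columns are shared covariates, which are outcomes, the weight column, and
any level recodes needed to harmonize the files; nothing is inferred.

Outputs mirror the study's reporting: a Rao-Scott weighted-vs-unweighted
comparison for every categorical covariate, the mass-imputed estimate per
imputer and outcome, and — when the probability file carries benchmark
outcome values — the bias of each estimate against the weighted benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd
import yaml

from .estimation import (
    bias as estimate_bias,
    mass_estimate,
    naive_estimate,
    rao_scott_compare,
    weighted_estimate,
)
from .fcs import ImputerSpec, mass_impute_fcs
from .latent import mass_impute_latent
from .sampling import SurveySample
from .schema import Schema, schema_from_dict, schema_to_dict


@dataclass(frozen=True)
class VariableMapping:
    """Declared alignment between the two input files."""

    covariates: dict  # name -> VariableSchema (shared columns)
    outcomes: dict    # name -> VariableSchema (nonprobability file only)
    weight_column: str = "weight"
    recodes: dict = field(default_factory=dict)  # column -> {old: new}

    @property
    def schema(self) -> Schema:
        return {**self.covariates, **self.outcomes}

    @classmethod
    def from_dict(cls, d: dict) -> "VariableMapping":
        return cls(
            covariates=schema_from_dict(d["covariates"]),
            outcomes=schema_from_dict(d["outcomes"]),
            weight_column=d.get("weight_column", "weight"),
            recodes=d.get("recodes", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "VariableMapping":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_sample(sample: SurveySample, path, schema_path=None) -> None:
    """Serialize a sample as CSV with a weight column (+ YAML schema sidecar)."""
    out = sample.data.copy()
    out["weight"] = sample.weights
    out.to_csv(path, index=False)
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            yaml.safe_dump(
                {name: spec for name, spec in schema_to_dict(sample.schema).items()
                 if name in sample.observed_columns},
                fh,
            )


def _apply_recodes(df: pd.DataFrame, recodes: dict) -> pd.DataFrame:
    for col, mapping in recodes.items():
        if col in df.columns:
            df[col] = df[col].map(lambda v: mapping.get(v, v))
    return df


def _validate_levels(df: pd.DataFrame, schema: Schema, label: str, columns) -> None:
    problems = []
    for name in columns:
        vs = schema[name]
        if name not in df.columns:
            problems.append(f"{label}: missing column {name!r}")
            continue
        if vs.is_discrete:
            bad = sorted(set(df[name].unique()) - set(vs.level_tuple()))
            if bad:
                problems.append(
                    f"{label}: column {name!r} has undeclared levels {bad}"
                )
    if problems:
        raise ValueError("variable mapping violations:\n" + "\n".join(problems))


def load_probability_sample(path, mapping: VariableMapping) -> SurveySample:
    df = _apply_recodes(pd.read_csv(path), mapping.recodes)
    if mapping.weight_column not in df.columns:
        raise ValueError(f"weight column {mapping.weight_column!r} not found")
    cov = list(mapping.covariates)
    _validate_levels(df, mapping.schema, "probability file", cov)
    # benchmark outcomes are kept if present but never used for imputation
    extra = [c for c in mapping.outcomes if c in df.columns]
    return SurveySample(
        unit_ids=np.arange(len(df)),
        weights=df[mapping.weight_column].to_numpy(dtype=float),
        observed_columns=tuple(cov),
        data=df[cov + extra].reset_index(drop=True),
        schema=mapping.schema,
    )


def load_nonprobability_sample(path, mapping: VariableMapping) -> SurveySample:
    df = _apply_recodes(pd.read_csv(path), mapping.recodes)
    cols = list(mapping.covariates) + list(mapping.outcomes)
    _validate_levels(df, mapping.schema, "nonprobability file", cols)
    return SurveySample(
        unit_ids=np.arange(len(df)),
        weights=np.ones(len(df)),
        observed_columns=tuple(cols),
        data=df[cols].reset_index(drop=True),
        schema=mapping.schema,
    )


@dataclass
class IntegrationReport:
    covariate_comparison: pd.DataFrame  # Rao-Scott test per categorical covariate
    covariate_tables: dict              # name -> side-by-side frequency table
    estimates: pd.DataFrame             # method x outcome (x level) estimates
    benchmark_bias: pd.DataFrame | None # present when the probability file has outcomes
    record_counts: dict


def _estimands(mapping: VariableMapping):
    for name, vs in mapping.outcomes.items():
        if vs.kind == "categorical":
            for lev in vs.levels:
                yield name, lev
        else:
            yield name, None


def integrate(
    probability_file,
    nonprobability_file,
    mapping: VariableMapping,
    imputer_specs: tuple = (ImputerSpec(method="pmm"),),
    seed: int | None = None,
) -> IntegrationReport:
    """End-to-end integration of two survey files."""
    sA = load_probability_sample(probability_file, mapping)
    sB = load_nonprobability_sample(nonprobability_file, mapping)
    root = np.random.default_rng(seed)

    rs_rows, rs_tables = [], {}
    for name, vs in mapping.covariates.items():
        if not vs.is_discrete:
            continue
        res = rao_scott_compare(sA, sB, name)
        rs_rows.append((name, res.statistic, res.df, res.p_value, res.design_effect))
        rs_tables[name] = res.table
    covariate_comparison = pd.DataFrame(
        rs_rows, columns=["variable", "statistic", "df", "p_value", "design_effect"]
    )

    est_rows = []
    for name, lev in _estimands(mapping):
        est_rows.append(
            ("naive", name, lev, naive_estimate(sB, name, lev).theta_hat)
        )
    for spec in imputer_specs:
        rng = np.random.default_rng(root.integers(0, 2**63))
        if spec.method == "latent_joint":
            mis = mass_impute_latent(sA, sB, spec, rng=rng)
        else:
            mis = mass_impute_fcs(sA, sB, spec, rng=rng)
        for name, lev in _estimands(mapping):
            est_rows.append((spec.label, name, lev, mass_estimate(mis, name, lev).theta_hat))
    estimates = pd.DataFrame(est_rows, columns=["method", "variable", "level", "estimate"])

    benchmark_bias = None
    bench_cols = [c for c in mapping.outcomes if c in sA.data.columns]
    if bench_cols:
        bench_sample = SurveySample(
            unit_ids=sA.unit_ids,
            weights=sA.weights,
            observed_columns=tuple(list(sA.observed_columns) + bench_cols),
            data=sA.data,
            schema=mapping.schema,
        )
        bias_rows = []
        for name, lev in _estimands(mapping):
            if name not in bench_cols:
                continue
            benchmark = weighted_estimate(bench_sample, name, lev).theta_hat
            for _, row in estimates[
                (estimates["variable"] == name)
                & (estimates["level"].fillna(-1) == (lev if lev is not None else -1))
            ].iterrows():
                bias_rows.append(
                    (row["method"], name, lev, benchmark,
                     estimate_bias(row["estimate"], benchmark))
                )
        benchmark_bias = pd.DataFrame(
            bias_rows, columns=["method", "variable", "level", "benchmark", "bias"]
        )

    return IntegrationReport(
        covariate_comparison=covariate_comparison,
        covariate_tables=rs_tables,
        estimates=estimates,
        benchmark_bias=benchmark_bias,
        record_counts={"probability": sA.n, "nonprobability": sB.n},
    )
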