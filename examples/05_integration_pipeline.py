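"""File-based integration: two CSV files + a variable mapping.

Simulates the real-world workflow: a weighted probability file with
covariates only and a nonprobability file with covariates + outcomes are
written to disk, then integrated end-to-end — Rao-Scott covariate
comparison, mass-imputed estimates, and (because this synthetic
probability file also carries benchmark outcomes) a bias report.
"""

import tempfile
from pathlib import Path

import numpy as np

import massimpute as mi
from massimpute.pipeline import VariableMapping, write_sample
from massimpute.schema import VariableSchema

rng = np.random.default_rng(5)
pop = mi.generate_population(mi.SuperPopulationConfig(N=10_000), rng)
sA = mi.draw_srswor(pop, 500, rng)
sB = mi.draw_poisson(pop, mi.calibrate_selection(pop), rng)

mapping = VariableMapping(
    covariates={
        "X1": VariableSchema("categorical", (1, 2, 3)),
        "X2": VariableSchema("continuous"),
        "X3": VariableSchema("continuous"),
    },
    outcomes={
        "X4": VariableSchema("binary"),
        "X5": VariableSchema("categorical", (1, 2, 3)),
        "X6": VariableSchema("binary"),
        "X7": VariableSchema("continuous"),
    },
)

with tempfile.TemporaryDirectory() as tmp:
    pa, pb = Path(tmp) / "probability.csv", Path(tmp) / "nonprobability.csv"
    # give the probability file benchmark outcome values so the pipeline
    # can also report biases (as when a benchmark survey observes them)
    bench = mi.SurveySample(
        unit_ids=sA.unit_ids, weights=sA.weights,
        observed_columns=tuple(pop.schema),
        data=pop.values.iloc[sA.unit_ids].reset_index(drop=True),
        schema=pop.schema,
    )
    write_sample(bench, pa)
    write_sample(sB, pb)

    report = mi.integrate(
        pa, pb, mapping,
        (mi.ImputerSpec(method="pmm", m=10), mi.ImputerSpec(method="latent_joint", m=10)),
        seed=17,
    )

print("record counts:", report.record_counts)
print("\nRao-Scott covariate comparison (weighted S_A vs unweighted S_B):")
print(report.covariate_comparison.to_string(index=False,
                                            float_format=lambda v: f"{v:.4f}"))
print("\nX1 side-by-side distribution:")
print(report.covariate_tables["X1"].to_string(index=False,
                                              float_format=lambda v: f"{v:.2f}"))
print("\nbenchmark bias per method and outcome:")
bb = report.benchmark_bias.copy()
bb["level"] = bb["level"].fillna("")
print(bb.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nA small Rao-Scott p-value flags a covariate whose weighted and"
    "\nunweighted distributions disagree (informative selection); the bias"
    "\ncolumn shows mass imputation shrinking the naive error."
)
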