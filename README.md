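# massimpute

Combining probability and nonprobability survey samples by multivariate
mass imputation.

## The problem

Convenience samples — opt-in panels, event-recruited health surveys, web
polls — observe rich outcome data but lack a sampling design, so their
unweighted ("naive") estimates can carry severe selection bias.  A
probability sample from the same population carries trustworthy design
weights but typically lacks the outcomes of interest.  **Mass imputation**
bridges the two: fit an outcome model f(Y | X) on the nonprobability
sample S_B (covariates X and outcomes Y observed), impute Y for every
unit of the probability sample S_A (covariates only, weights w_i), and
estimate the population mean of each outcome by the survey-weighted mean
of the imputations,

    θ̂ = N̂⁻¹ Σ_{i∈S_A} w_i Y*_i,   N̂ = Σ_{i∈S_A} w_i,

averaged over m = 10 multiply-imputed completions.  This is the workflow
used to integrate convenience health surveys (e.g. a tribal behavioral
risk factor survey) with weighted national surveys (e.g. BRFSS).

The package is aimed at survey statisticians and epidemiologists who want
to (a) run the full Monte Carlo evaluation of multivariate mass-imputation
methods on a configurable synthetic design, and (b) apply the same
machinery to their own probability/nonprobability file pairs.

Two families of multivariate imputers are provided:

* **FCS** (fully conditional specification): cycle one conditional model
  per outcome given covariates and the other outcomes — predictive mean
  matching (`pmm`), a classification/regression tree (`cart`), or a
  bagged forest with leaf-donor draws (`rf`);
* **latent joint**: a GERBIL-inspired latent Gaussian model — ordered
  probit thresholds for discrete outcomes, linear-Gaussian conditionals
  for continuous ones, a triangular factorization fitted by Gibbs data
  augmentation, drawing all outcomes simultaneously.

Plus survey-weighted estimation, Monte Carlo bias aggregation, and a
Rao-Scott-corrected weighted-vs-unweighted covariate comparison.

## Worked example

```python
import numpy as np
import massimpute as mi

rng = np.random.default_rng(21)
pop = mi.generate_population(mi.SuperPopulationConfig(N=10_000), rng)
sA = mi.draw_srswor(pop, 500, rng)                               # weights N/n = 20
model = mi.calibrate_selection(pop, (0.6, 0.3, 0.1), 500)        # informative selection
sB = mi.draw_poisson(pop, model, rng)

truth = pop.mean("X7")
naive = mi.naive_estimate(sB, "X7").theta_hat
mis = mi.mass_impute_fcs(sA, sB, mi.ImputerSpec(method="pmm", m=10, seed=4))
mass = mi.mass_estimate(mis, "X7").theta_hat
print(f"truth {truth:.3f}  naive {naive:.3f}  mass-imputed (pmm) {mass:.3f}")
```

Output:

```
truth 1.610  naive 2.671  mass-imputed (pmm) 1.637
```

The naive nonprobability mean of X7 overshoots the population value by
more than one unit because selection favors units with large X1–X3 (which
correlate with X7); the pmm mass-imputed estimate, carried by the
probability sample's design weights, lands within ~0.03 on a single
replicate, and its bias averaged over Monte Carlo replicates is about
+0.02 (see the study tables and docs/methods.md).

The `examples/` directory has one short script per capability: population
generation against its closed-form moments, the selection-bias anatomy of
the two samples, a four-method single-replicate comparison, a desk-scale
Monte Carlo study, and the file-based integration pipeline with its
Rao-Scott covariate report.

A thin CLI wraps the two shell-level workflows:

```bash
massimpute mc-study --reps 200 --seed 1 --out results/study/
massimpute integrate --probability a.csv --nonprobability b.csv \
    --mapping mapping.yaml --out results/integration/
```

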