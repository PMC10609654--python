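"""Anatomy of selection bias: probability vs nonprobability sample means.

Draws the SRSWOR probability sample (design weights N/n) and the Poisson
nonprobability sample whose inclusion depends on X1, X2, X3, then compares
weighted, naive and true means — the covariate-comparison table of the
simulation study.
"""

import numpy as np

import massimpute as mi

rng = np.random.default_rng(7)
pop = mi.generate_population(mi.SuperPopulationConfig(N=10_000), rng)
sA = mi.draw_srswor(pop, 500, rng)
model = mi.calibrate_selection(pop, (0.6, 0.3, 0.1), 500)
sB = mi.draw_poisson(pop, model, rng)

print(f"n_A = {sA.n} (weights {sA.weights[0]:.0f}), realized n_B = {sB.n}")
print(f"{'estimand':<10}{'population':>11}{'weighted S_A':>13}{'naive S_B':>11}")
rows = [("X1", 1), ("X1", 2), ("X2", None), ("X3", None)]
for var, lev in rows:
    w = mi.weighted_estimate(sA, var, lev).theta_hat
    n = mi.naive_estimate(sB, var, lev).theta_hat
    label = var if lev is None else f"P({var}={lev})"
    print(f"{label:<10}{pop.mean(var, lev):>11.3f}{w:>13.3f}{n:>11.3f}")

print(
    "\nThe weighted probability-sample column tracks the truth; the naive"
    "\nnonprobability column over-represents high-X1/X2/X3 units, the"
    "\nselection bias that mass imputation is designed to remove."
)
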