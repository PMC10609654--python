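"""Desk-scale Monte Carlo study: bias and variance per method x estimand.

Runs M = 25 replicates of the full pipeline (population, both samples,
all four imputers) and prints the bias table.  The shipped default is
M = 200; the full-scale study uses M = 1000 via `StudyConfig(M=1000)` or
`massimpute mc-study --reps 1000`.
"""

import massimpute as mi

config = mi.StudyConfig(M=25, seed=42)
result = mi.run_study(config, progress=True)

table = result.table2()
table["level"] = table["level"].fillna("")
print("\nMonte Carlo results (M = %d):" % result.M)
print(
    table.sort_values(["variable", "level", "method"]).to_string(
        index=False, float_format=lambda v: f"{v:.4f}"
    )
)
print(
    "\nmc_bias is the mean of (estimate - population truth) over replicates;"
    "\nat this small M its Monte Carlo SE is a few thousandths, enough to see"
    "\nthat pmm/latent_joint are nearly unbiased while the tree methods keep"
    "\na pull toward the selection-biased donor marginal (largest for rf X7)."
)
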