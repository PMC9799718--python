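"""Proportional-intensity covariate effects (hazard ratios per transition).

Simulates a cohort in which females leave MHOW for MHNW at twice the male
rate (beta = log 2 on that single edge), fits the covariate model
q_rs(z) = q_rs(0) exp(beta_rs' z), and prints the recovered hazard ratios
for the weight-improvement and metabolic-deterioration edges.
"""

import numpy as np

from metatrans import (
    GeneratorConfig,
    ModelSpec,
    fit,
    hazard_ratio_table,
    simulate_cohort,
    six_state_structure,
)

edges = six_state_structure().edge_list
beta = np.zeros((14, 1))
beta[edges.index((1, 0)), 0] = np.log(2.0)  # MHOW -> MHNW, females twice as fast

cfg = GeneratorConfig(
    n_subjects=2000, seed=3, covariates=("female",), beta=beta,
    visit_count=6, interval_jitter_sd=0.0,
)
cohort = simulate_cohort(cfg)
fitted = fit(cohort.panel, ModelSpec(covariates=("female",)))

hr = hazard_ratio_table(fitted)
show = hr[
    ((hr["from"] == "MHOW") & (hr["to"] == "MHNW"))
    | ((hr["from"] == "MHNW") & (hr["to"] == "MUNW"))
    | ((hr["from"] == "MUNW") & (hr["to"] == "MHNW"))
]
print("Hazard ratios (female vs male) with 95% CI:")
print(show.round(3).to_string(index=False))
print()
print("The MHOW->MHNW ratio should sit near the generating value 2.0 with a")
print("CI excluding 1; the other edges carry no true effect, so their HRs")
print("should hover around 1.0.")
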