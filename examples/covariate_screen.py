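"""Stepwise covariate screening on synthetic data.

Runs a forward-inclusion step (dOFV > 6.63) for a weight-on-clearance power
effect on two datasets: one generated WITH such an effect (and modest
unexplained IIV, so the signal is detectable) and one generated without it.
"""

from dataclasses import replace

import numpy as np

from rivapk import CovariateEffect, fit_foce, forward_select, study
from rivapk.cohort import generate_cohort, generate_dataset

base_model = study.final_model()
small_iiv = (float(np.log1p(0.25**2)),) + base_model.omega2[1:]
effect = CovariateEffect("cl_f", "WT", "power", theta_cov=2.0, cov_median=62.0)

cfg = study.study_design(seed=77)
cohort = generate_cohort(cfg)
with_eff = generate_dataset(cohort, replace(base_model, omega2=small_iiv,
                                            covariate_effects=(effect,)), cfg, seed=78)
without = generate_dataset(cohort, replace(base_model, omega2=small_iiv), cfg, seed=78)

candidate = CovariateEffect("cl_f", "WT", "power", theta_cov=0.1, cov_median=62.0)
for label, ds in (("data WITH weight effect", with_eff),
                  ("data WITHOUT weight effect", without)):
    base = fit_foce(ds.table, base_model, compute_se=False, polish=False)
    sel = forward_select(ds.table, base, [candidate], polish=False)
    print(f"\n{label}:")
    print(sel.trace.to_string(index=False))
print("\nA candidate is included only when it drops the objective function by")
print("more than 6.63 (p < 0.01, 1 df); at the study's full unexplained IIV of")
print("61.5% even a sizeable weight effect carries too little signal for 38")
print("subjects — consistent with the reference analysis retaining no covariate.")
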