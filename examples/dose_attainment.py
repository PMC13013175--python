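"""Monte-Carlo dose-attainment simulation against bleeding-risk thresholds.

Draws 1,000 virtual post-TIPS patients per once-daily dose from the final
population model, drives each to steady state, and reports the percentage
whose exposure stays within BOTH safety limits (AUC over one day
<= 1.77 mg·h/L and peak concentration <= 140 µg/L).
"""

from rivapk import study
from rivapk.plots import plot_exposure_boxes

table, results = study.reference_simulation(n=1000, seed=2026)
print(table[["dose", "n", "percent_both", "frac_auc", "frac_cmax", "mc_se"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))

print("""
percent_both is the fraction of virtual patients meeting BOTH exposure
criteria; it falls steeply with dose because the steady-state peak crosses
the 140 µg/L bleeding-risk limit first (the post-TIPS volume of distribution
is small, so peaks are high).  The published analysis reported 84/66/55/28%
at 5/7.5/10/15 mg under the same design.  mc_se is the binomial Monte-Carlo
standard error of the joint fraction.
""")
plot_exposure_boxes(results, study.SAFETY_THRESHOLDS).savefig("exposure.png", dpi=120)
print("wrote exposure.png (box plots of AUC and Cmax per dose vs the limits)")
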