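"""Cohort-level lesion-load statistics on a simulated covariate table.

Simulates a three-group cohort (controls, presymptomatic and symptomatic
mutation carriers) with planted multiplicative group effects and annual
accrual on log lesion volume, then runs the analysis stack: percent-excess
OLS, the random-intercept/random-slope mixed model, residual Spearman
correlation with cognition, and severity stratification.
"""

import numpy as np

from wmh_bullseye import (CohortSpec, cohort_summary, fit_cross_sectional,
                          fit_longitudinal, generate_cohort_table,
                          occupancy_percent, residual_spearman,
                          severity_table)
from wmh_bullseye.stats import accrual_percent_per_year

cspec = CohortSpec(rng_seed=42, visits_per_subject=3,
                   cognition_loading=-0.8)
table = generate_cohort_table(cspec)
print(f"{table.subject_id.nunique()} subjects, {len(table)} subject-visits")

print("\ndemographics:")
print(cohort_summary(table)[["group", "n", "percent_female",
                             "age_mean"]].to_string(index=False))

res = fit_cross_sectional(table, outcome="log_wmh")
print("\ncross-sectional group effects (percent excess vs controls):")
for term, (pt, ci) in res.percent_excess.items():
    if "group" in term:
        name = term.split("T.")[1].rstrip("]")
        print(f"  {name:15s} {pt:6.1f}% [{ci[0]:.1f}, {ci[1]:.1f}]  "
              f"p={res.pvalues[term]:.3f}")
print(f"planted: presymptomatic +17.8%, symptomatic +48.2%")

longi = fit_longitudinal(table, outcome="log_wmh")
print("\nlongitudinal accrual (%/year):")
for g in ("control", "presymptomatic", "symptomatic"):
    print(f"  {g:15s} {accrual_percent_per_year(longi, g):6.2f}")
print("planted: 4.32, 1.68, 9.16 %/year")

rho, p = residual_spearman(table, "log_wmh", "digit_span")
print(f"\nadjusted lesion load vs digit span: rho={rho:+.2f} (p={p:.2g}) "
      "— negative by construction")

print("\nseverity stratification of carriers "
      f"(thresholds 1000/2500 mm3 = {occupancy_percent(1000, 1400)}%/"
      f"{occupancy_percent(2500, 1400)}% of a 1400 ml TIV):")
print(severity_table(table).to_string(index=False))
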