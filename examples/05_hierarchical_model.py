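"""Full analysis: moderated hierarchical regression and simple slopes.

Runs the complete chain on the default synthetic cohort (9 participants,
47 five-week windows) and prints the three-step model for stress increase
plus the buffering profile of the HRVsd coefficient across HRV-trend values.
"""

import numpy as np

from hrvstress import (
    assemble_windows,
    build_daily_table,
    fit_hierarchical,
    simple_slopes,
    standardize,
    windows_table,
)
from hrvstress.association_models import simple_slope_table
from hrvstress.questionnaire import score_table
from hrvstress.synthetic import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=1))
daily = build_daily_table(cohort.nightly_hrv, cohort.ema, cohort.activity)
table = windows_table(assemble_windows(daily, score_table(cohort.responses)))
sample = standardize(table)

fit = fit_hierarchical(sample, "stress_increase")
print(f"stress increase, n = {sample.n} windows (grand-mean standardized)\n")
for step in fit.steps:
    print(f"step {step.step}: R² = {step.r2:.3f}  adj R² = {step.adj_r2:.3f}  "
          f"F = {step.f_stat:.2f} (p = {step.f_pvalue:.3f})")
    for term in step.terms:
        print(f"    β {term:<16} {step.params[term]:+.3f}  (p = {step.pvalues[term]:.3f})")
print()
for k in (2, 3):
    print(f"step {k - 1} -> {k}: ΔR² = {fit.delta_r2[k]:.3f}, ΔF = {fit.delta_f[k]:+.3f}, "
          f"partial-F p = {fit.comparison_p[k]:.3f}")

profile = simple_slopes(fit, np.array([-1.0, 0.0, 1.0]))
print("\nconditional HRVsd coefficient by HRV uptrend (simple slopes):")
print(simple_slope_table(profile).round(3).to_string(index=False))
print()
print("The coefficient shrinks as the HRV trend rises: an uptrend in nightly")
print("HRV buffers the association between rising day-to-day HRV fluctuation")
print("and stress increase — the interaction pattern the analysis probes.")
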