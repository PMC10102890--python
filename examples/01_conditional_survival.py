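"""Conditional 5-year survival and restricted mean residual lifetime.

Simulates a registry-style cohort with constant cause-specific hazards
(cancer 0.3/yr, other causes 0.1/yr), estimates the conditional 5-year
survival CS(t+5 | t) and the restricted mean residual lifetime
RMRL(t+5 | t) with 95% confidence intervals, and compares them to the
analytic truths of the generating law.
"""
import numpy as np

from survode import conditional_survival, crmtl, rmrl
from survode.simulate import ScenarioSpec, generate_cohort, truth

spec = ScenarioSpec(
    n=2000, lambda_cancer=0.3, lambda_other=0.1,
    censoring_rate=0.1, admin_censor_time=20.0, seed=1,
)
cohort = generate_cohort(spec)
delta = 5.0
ts = [0.0, 1.0, 2.0, 3.0]

cs = conditional_survival(cohort, delta, t_grid=ts, horizon=9.0)
rm = rmrl(cohort, delta, t_grid=ts, horizon=9.0)
lost = crmtl(rm)

print(f"n = {cohort.n}, Delta = {delta} years")
print("t    CS(t+5|t)  [95% CI]          truth   RMRL(t+5|t)  years lost")
for i, t in enumerate(ts):
    print(
        f"{t:3.0f}  {cs.estimate[i]:.3f}  [{cs.ci_lower[i]:.3f}, {cs.ci_upper[i]:.3f}]"
        f"   {truth(spec, 'cs', t, delta):.3f}"
        f"   {rm.estimate[i]:.2f} ± {1.96 * rm.se[i]:.2f}"
        f"     {lost.estimate[i]:.2f}"
    )

print(
    "\nA constant hazard is memoryless, so every row shares the same truth:"
    f" CS = {truth(spec, 'cs', 0, delta):.3f} and"
    f" RMRL = {truth(spec, 'rmrl', 0, delta):.2f} years lived out of {delta:.0f};"
    " the estimates fluctuate around it within their confidence intervals."
)
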