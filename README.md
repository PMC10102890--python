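# survode

Plug-in ODE estimators for the prognosis of cancer survivors.

## The problem

A patient who has already survived *t* years after a cancer diagnosis is
not well served by the survival curve drawn from the day of diagnosis.
Registry analysts and clinicians instead want parameters conditioned on
being alive at *t*: the **conditional Δ-year survival**

    CS(t+Δ | t) = P(T > t+Δ) / P(T > t),

the **restricted mean residual lifetime** (expected years lived in the
next Δ years)

    RMRL(t+Δ | t) = ∫ₜ^{t+Δ} P(T > s) ds / P(T > t),

its complement the **restricted mean time lost** Δ − RMRL, and, when the
cause of death is recorded, the cause-specific risk
P(T < t+Δ, D = cancer | T ≥ t) together with its ratio, difference, and
proportion variants against death from other causes.  Finally, the
cohort can be contrasted with its demographic twin in the general
population: CS and RMRL ratios and differences against Ederer I expected
survival from national rate tables.

## The method

All of these parameters are functionals of processes X that solve an
integral equation driven by a vector A of cumulative hazards,

    X(t) = X(0) + ∫₀ᵗ F(X(s)) dA(s).

Replacing A with its Nelson–Aalen estimate Â turns the equation into a
pathwise difference equation whose solution X̂ is the plug-in estimator
(for survival, exactly Kaplan–Meier).  The sampling covariance V̂(t) of
√n (X̂ − X) is propagated alongside by a companion recursion with a
correction term driven by the quadratic covariation of the hazard
increments, a cross-covariance recursion links V̂(t) to V̂(t, t+Δ), and
the covariance of any smooth functional H(X̂(t), X̂(t+Δ)) follows by the
delta method.  Everything is generic: adding a new prognosis parameter
means writing down (X(0), F, ∇F, H, ∇H); the variance machinery comes
for free.  For every shipped parameter the generic variance is also
evaluated through its independently printed closed form and the two are
asserted to agree to 1e-10 at run time.

## Worked example

```python
from survode import conditional_survival, rmrl, crmtl
from survode.simulate import ScenarioSpec, generate_cohort, truth

spec = ScenarioSpec(n=2000, lambda_cancer=0.3, lambda_other=0.1,
                    censoring_rate=0.1, admin_censor_time=20.0, seed=1)
cohort = generate_cohort(spec)
cs = conditional_survival(cohort, delta=5.0, t_grid=[0.0, 1.0], horizon=9.0)
print(cs.estimate, cs.ci_lower, cs.ci_upper)
print("truth:", truth(spec, "cs", 1.0, 5.0))
```

prints

```
[0.14285955 0.14922005] [0.12479881 0.12551707] [0.1609203  0.17292304]
truth: 0.1353352832366127
```

the estimated conditional 5-year survival at diagnosis and after one
survived year, each with a 95% Wald interval from the analytic variance,
fluctuating around the memoryless truth e^(-0.4·5) ≈ 0.135 of the
constant-hazard generator.  `examples/` contains one narrative script
per capability (conditional survival and RMRL, cause-specific risks,
population contrasts, and the time-until-prognosis-level report); each
generates its own synthetic input and explains the numbers it prints.

A thin CLI covers file-based workflows:

```bash
survode simulate scenario.yaml --out-dir run
survode estimate run/cohort.tsv --params cs,rmrl,risk --delta 5 --out-dir run
survode contrast run/cohort.tsv run/ratetable.tsv --delta 5 --out-dir run
survode report run/contrast_cs_ratio.tsv --levels 0.8,0.9,0.95
```

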