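# bcellfate

Population-dynamics modelling of B-cell fate bifurcation after a
T-dependent immunization: where do marginal-zone B cells made during an
immune response come from, and how long do they last?

A Cre-switched CAR reporter marks B cells activated during the response; a
Notch2-knockout strain (N2KO) deletes Notch2 in exactly those cells.
`bcellfate` fits a family of compartment ODE models to cross-sectional
per-mouse counts of CAR+ germinal-center B (GCB) and CAR+ marginal-zone B
(MZB) cells in control and N2KO mice, ranks the models by leave-one-out
cross-validation weight, and derives the quantities the models make
interpretable: source-resolved influx into the CAR+ MZB pool, and the
clonal half-life of CAR+ MZB cells in each genotype.

It is aimed at quantitative immunologists analysing immunization
time-courses, and ships a synthetic-cohort generator so the entire pipeline
is testable end to end without access to mouse data.

## The models

All family members share the GCB equation, driven by the empirically
described total follicular-B pool F(t):

    dG/dt = alpha(t) F(t) - delta(t) G

and differ in where CAR+ MZB cells (M) come from:

    branched:  dM/dt = mu(t) F(t) + beta(t) Mneg(t) - lambda M
    linear:    dM/dt = mu(t) G(t) + beta(t) Mneg(t) - lambda M
    null:      dM/dt =              beta(t) Mneg(t) - lambda M

with Mneg(t) the CAR- MZB pool and beta a per-capita activation rate.  In
N2KO mice mu = 0 (activation deletes Notch2) and the loss rate is lambda':

    dM_n2/dt = beta(t) Mneg(t) - lambda' M_n2

Time-varying rates follow the sigmoid `scale / (1 + exp(nu (t - t0)^2))`
anchored at t0 = 4 days post-immunization.  Three topologies x three rate
variants (neutral, time-varying influx, time-varying GCB loss) plus a
time-varying-mu branched variant give a ten-member family.  Fitting is
Bayesian (log-normal observation noise, ensemble MCMC); model ranking uses
PSIS-LOO with pseudo-BMA+ percentage weights; clonal half-life is
ln(2)/net-loss-rate, propagated per posterior draw.  See
`docs/methods.md` for priors, sampler design and numerical choices.

## Worked example

```python
import numpy as np
import bcellfate as bf

# simulate a cohort at the study design, then run the standard analysis
data, truth = bf.generate(bf.CohortDesign(seed=7))
sources = bf.fit_sources_from_cohort(data)
model = bf.BCellFateModel(model="branched_tvi", seed=7, draws=2500, tune=2500)
model.fit(data, sources=sources)

summary = model.summary_.set_index("parameter")
for name in ("lambda_ctrl", "lambda_n2ko", "mu", "beta0",
             "influx_halving_time", "half_life_ctrl", "half_life_n2ko"):
    row = summary.loc[name]
    print(f"{name:>20s}: {row['median']:.4g}  "
          f"(95% CI {row['ci_low']:.4g} - {row['ci_high']:.4g})")

decomp = bf.influx_decomposition(model, np.arange(4.0, 26.0))
print(f"day-4 MZB-activation share of influx: "
      f"{decomp.summary.loc[0, 'cum_share_carneg_median']:.0f}%")
```

prints

```
         lambda_ctrl: 0.3937  (95% CI 0.1093 - 1.461)
         lambda_n2ko: 1.036  (95% CI 0.4859 - 2.193)
                  mu: 0.0004701  (95% CI 9.231e-05 - 0.002017)
               beta0: 0.008805  (95% CI 0.003296 - 0.02047)
 influx_halving_time: 11.72  (95% CI 7.986 - 16.94)
      half_life_ctrl: 1.76  (95% CI 0.4746 - 6.344)
      half_life_n2ko: 0.6693  (95% CI 0.316 - 1.427)
day-4 MZB-activation share of influx: 38%
```

Reading this: the knockout loss rate `lambda_n2ko` (1.04/day) is clearly
above the control rate `lambda_ctrl` (0.39/day) — CAR+ MZB clones halve in
about 0.7 days without Notch2 versus ~1.8 days with it — and the influx
into the CAR+ MZB pool shifts from MZB activation early (≈38% at day 4
here) toward FoB differentiation as the response matures.  This cohort was
simulated with `lambda = 0.49`, `lambda' = 0.94`, `mu = 1/1430` and
`beta0 = 1/150` per day; every generating value lies inside its 95%
credible interval.  Medians wander seed-to-seed within those (wide,
honestly reported) intervals because the late-time data pin ratios such as
`mu/lambda` more sharply than the individual rates.

The same pipeline is scriptable from the shell:

```sh
bcellfate simulate --seed 7 --out cohort.csv
bcellfate all --cohort cohort.csv --seed 7 --out-dir results/run1
```

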