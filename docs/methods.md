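# Methods

## The biological question and the model family

After a T-dependent immunization, antigen-activated follicular B cells (FoB)
can enter the germinal-center reaction (GCB) or acquire a marginal-zone
phenotype (MZB).  A Cre-switched CAR reporter marks cells activated during
the response, and a Notch2-knockout strain (N2KO) removes Notch2 exactly in
those activated cells, so CAR+ GCB and CAR+ MZB counts in control and N2KO
mice trace where newly made MZB cells come from and how long they persist.

`bcellfate` implements deterministic compartment models for the two CAR+
pools.  Every model shares the GCB equation

```
dG/dt = alpha(t) * F(t) - delta(t) * G,
```

with `F(t)` the (empirically described) total FoB pool.  The CAR+ MZB
equation differs by topology:

| topology | dM/dt |
|----------|-------|
| branched | `mu(t)*F(t) + beta(t)*Mneg(t) - lambda*M` |
| linear   | `mu(t)*G(t) + beta(t)*Mneg(t) - lambda*M` |
| null     | `beta(t)*Mneg(t) - lambda*M` |

`Mneg(t)` is the CAR- MZB pool and `beta` is a per-capita activation rate
(so the influx is `beta*Mneg`; the per-capita convention matches the day^-1
units in which the activation rate is reported).  In N2KO mice activation
deletes Notch2, so `mu = 0` and the loss rate is `lambda'`:

```
dM_n2/dt = beta(t)*Mneg(t) - lambda' * M_n2.
```

Time-varying rates use the even sigmoid `scale / (1 + exp(nu*(t-t0)^2))`,
anchored at `t0 = 4` days post-immunization (counts are indistinguishable
between groups up to day 4, which is also why the initial conditions are
taken there).  The family is the 3x3 grid of topologies x {neutral,
time-varying influx (`alpha`, `beta` share one `nu`), time-varying GCB loss}
plus a branched time-varying-influx variant whose `mu` also varies in time
(sharing the same `nu`), ten models in all.

Two conventions worth making explicit:

- **Halving time.** For a sigmoid rate the value at `t0` is `scale/2`; we
  report the time for the rate to halve *relative to its value at the
  anchor*, `dt_half = sqrt(ln 3 / nu)` (since `1 + e^{nu dt^2} = 4` there).
- **Shared `nu`.** The reference (branched, time-varying-influx) model fits
  one shared shape parameter for `alpha(t)` and `beta(t)`; separate shapes
  are available via `shared_nu=False`.

## Driver-pool curves

`F(t)` and `Mneg(t)` are exogenous forcings, described by a four-parameter
log-scale Gaussian bump, `log N(t) = c0 + c1*exp(-c2*(t-c3)^2)`, least-
squares fitted to log counts (multiplicative inter-mouse noise), with a
natural cubic smoothing-spline alternative.  The bump amplitude is bounded
(`|c1| <= 3`) and the inverse-width capped (`c2 <= 0.08 day^-2`, i.e. an
excursion no narrower than a few days): the curve is meant to describe a
smooth trend at the sampling resolution, not to interpolate per-day noise.
Outside the observed day range the curves clamp to their boundary values,
keeping every evaluator positive and continuous.  When only total MZB counts
are available, CAR- MZB is the total minus the CAR+ count.

## Observation model and priors

Counts are fitted on the natural-log scale: `ln y ~ Normal(ln prediction,
sigma)`, one `sigma` per observed (group, population) series.  Zero counts
are replaced by half the smallest positive count of that population (with a
logged warning).  The GCB trajectory is shared between genotypes; control
MZB uses `lambda`, N2KO MZB uses `lambda'` and no `mu` influx.

Priors (all positive parameters sampled as `theta = ln x`):

| parameter | prior | why |
|-----------|-------|-----|
| `alpha0` | logN(ln 3e-3, 2.0) | per-capita recruitment, order 1e-4..1e-2/day |
| `beta0`  | logN(ln 5e-3, 2.0) | per-capita activation, same order |
| `mu`     | logN(ln 1e-3, 2.0) | per-capita differentiation |
| `delta0`, `lambda`, `lambda'` | logN(ln 0.3, 1.5) | activated-B loss rates, order 0.05..2/day |
| `nu` | half-Normal(0, 0.1 day^-2) | shape; halving times of days-to-weeks |
| `G0`, `M0` | logN(day-4 geometric mean, 1.0) | anchored but weak: the same day-4 mice enter the likelihood, so the prior must not double-count them |
| `M0_n2` | logN(control day-4 geometric mean, 0.5) | the N2KO design starts at day 7; because groups are indistinguishable up to day 4, the control day-4 mean is a genuine external anchor for this pool, with width ~ its ln-scale standard error plus a group-difference allowance |
| `sigma` | half-Normal(0, 1) | ln-count noise |

The `M0_n2` anchor matters: the knockout pool collapses to its influx-driven
quasi-steady level before the first N2KO observation day, so `lambda'` is
identified almost entirely by the drop from the anchored day-4 value.

## Sampling

The likelihood is cheap (each evaluation is one fixed-grid solve, see below),
so the posterior is explored with an affine-invariant ensemble sampler.
The posterior has strong log-scale ridges — the data pin quasi-steady ratios
such as `mu/lambda` and `beta0/lambda'` more sharply than either factor — so
the sampler works in a whitened space: the mode is found by Nelder-Mead plus
L-BFGS-B, the Hessian of the negative log-posterior is evaluated there by
finite differences, and walkers move in the coordinates of its regularised
inverse Cholesky factor.  Moves are a differential-evolution mixture (80%
DE at two gammas, 20% snooker), which traverses the remaining nonlinear
ridge structure far better than stretch moves.  Defaults: 1500 warm-up +
1500 retained steps, walkers = max(2*dim+4, 24), thinned to ~2000 draws.
Walkers are treated as chains for split-R-hat and effective sample size; a
fit with any free-parameter R-hat >= 1.01 is flagged (warning status, never
a silent return).  Identical seeds give identical posteriors.

Per-observation pointwise log-likelihoods are recomputed for every retained
draw and attached to the ArviZ `InferenceData`, so PSIS-LOO and model
weights (pseudo-BMA+ with a seeded Bayesian bootstrap by default; stacking
optional) come straight from the standard estimators.  Observations with
Pareto k > 0.7 are flagged.

## Numerics

- **Reference solver**: adaptive stiff-capable LSODA at rtol 1e-8 / atol
  1e-10; requested output times are solver nodes.
- **Inference solver**: each equation is a forced linear scalar ODE, so a
  fixed-grid exponential integrator (coefficients frozen at step midpoints;
  each step solved exactly for the frozen coefficients) is used inside the
  sampler.  It is machine-exact for constant coefficients, O(dt^2) for
  time-varying ones, and ~1000x faster than the adaptive solver at dt =
  0.05 day.  Requested times are inserted as grid nodes, so no interpolation
  error is added.  Both solvers are cross-checked against each other, a
  fixed-step RK4 oracle and the closed-form null-model solution.
- The sigmoid underflows to a rate of exactly 0 once `nu*(t-t0)^2 >= 700`
  (never NaN); trajectories are floored at 0 against solver round-off;
  `|ln parameter| > 25` is rejected outright during sampling.

## Synthetic cohorts

The generator emulates the study's cross-sectional design: control mice at
days {4,7,9,14,17,22,26,30} with per-day n {3,9,3,15,3,5,4,6} (48 mice) and
N2KO mice at days {7,9,14} with n {7,5,6} (18 mice); each mouse contributes
one count per population at a single day.  Ground truth defaults: the
branched time-varying-influx model with `mu = 1/1430`, `beta0 = 1/150`,
`lambda = 0.49`, `lambda' = 0.94` (all per day), halving time 14.2 days,
`delta0 = 0.25`, `alpha0 = 5e-3`, pools `G0 = 1e4`, `M0 = M0_n2 = 2.5e4`
(the groups are indistinguishable at the day-4 anchor, so the knockout pool
starts at the control value).  Driver pools are log-Gaussian bumps around
1.5e7 FoB and 1e6 CAR- MZB cells — textbook splenic magnitudes — with mild
mid-response excursions.  Noise is log-normal per mouse: sd 0.5 on ln counts
for the CAR+ compartments (matching the visual spread of such data), 0.25
and 0.2 for the CAR- MZB and FoB pools.

What the generator does *not* emulate: gating/compensation error, per-mouse
random effects shared across populations, sex or cage effects, and any
misspecification of the ODE family itself.  Passing recovery tests therefore
demonstrates that the inference machinery is calibrated when the model is
correct — not that the model is correct for real mice.

## Identifiability and what the tests check

With the study's sampling days, the control CAR+ MZB pool is near quasi-
steady after the first week, so the data identify `mu*F/lambda` (the level)
much more sharply than `lambda` (the relaxation rate).  Consequently the
95% interval for `lambda` alone stays wide at any cohort size, while the
identified combinations contract as n grows; the contraction test asserts
narrowing of `ln(mu/lambda)` and of `sigma`, and the recovery tests assert
calibrated coverage and the `lambda' > lambda` sign at the study design.

Model selection by LOO weight recovers a branched-generated truth reliably.
The symmetric null-generated check is intrinsically hard: the branched and
linear models nest the null (`mu -> 0`), so their posterior predictive
distributions converge to the null's and the elpd gap shrinks to roughly the
effective-parameter penalty (~0.5-1 nat), the same order as elpd estimation
noise — a known weakness of LOO-style selection among nested models.  The
corresponding test asserts the strict top-weight threshold and is expected
to sit at its edge.

## Scaled-down problem sizes

Test-suite runs use reduced sampler budgets chosen as the package's own
trade-off between statistical resolution and turnaround: 20 recovery
replicates at 2500+2500 steps, model-selection replicates at 400-1000 steps,
and smoke fits at 400 steps.  The acceptance script fits the ten-model
family at 600+600 steps and refits the reference model at 2500+2500.
Production analyses should raise `draws`/`tune` until `converged_` is True
(all R-hat < 1.01).

## Known limitations

- Fitted driver-pool curves are treated as fixed when passed to the ODE fit;
  their uncertainty is not propagated (the recovery experiments therefore
  pass the generator's true curves, while the acceptance script refits them
  from the cohort as a real analysis would).
- The ensemble sampler's R-hat rarely reaches < 1.01 at reduced budgets;
  medians and 95% intervals are nevertheless stable (verified against
  12000-step runs), and the convergence flag reports the honest status.
- Single-cell heterogeneity, memory compartments, affinity maturation and
  spatial architecture are outside the model family by construction.
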