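# dapapkpd

Population pharmacokinetic-pharmacodynamic (PK-PD) modelling of once-daily
oral dapagliflozin, an SGLT2 inhibitor, and its HbA1c-lowering effect in
patients with type 2 diabetes — built for pharmacometricians who want a
fully scriptable, testable re-implementation of a real-world long-term
(1-year) population analysis: structural models, a FOCE-type mixed-effects
estimator, stepwise covariate selection, pc-VPC and bootstrap
qualification, dose-scenario simulation, and a synthetic-cohort generator
that emulates the study's data structure (85 patients, trough-only drug
sampling and HbA1c at visits near months 1, 3, 6, 9 and 12).

## Models

**PK.** One-compartment disposition with first-order absorption under
repeated once-daily dosing; trough-only sampling fixes the absorption rate
(ka = 57.4 /day) and apparent volume (V/F = 73.9 L), leaving the apparent
clearance to be estimated with a body-weight power covariate and a
log-normal random effect:

    CL/F_i = θ_CL · (BW/77.0)^θ_BW · exp(η_i),   η_i ~ N(0, ω²)

Concentrations are closed-form superpositions of single-dose curves, with
CL/F re-evaluated per dosing interval as body weight changes.

**PD.** HbA1c (%) follows an indirect-response (turnover) model with
zero-order production k_in and first-order loss k_out = ln2 / t½; at
baseline dH(0) = 0, hence k_in = k_out · H(0) with H(0) fixed to each
subject's observed baseline. The drug subtracts a saturable lowering rate
driven by the plasma concentration C(t):

    dH/dt = k_in − Efc(t) · (H − 5.0)/(8.0 − 5.0) − k_out · H
    Efc(t) = Emax · C(t) / (EC50 + C(t))

so Emax (%/day) is the maximal lowering rate for a patient at the 8.0%
reference baseline and the effect vanishes at the 5.0% normoglycaemic
floor. The ODE is linear in H given C(t); the package integrates it with
an exact per-day exponential update (quadrature for the time-varying
coefficients), cross-checked against an adaptive Runge-Kutta solver.

**Estimation.** FOCE with interaction: a Laplace-type approximation to the
marginal likelihood at each subject's conditional mode, optimised over
fixed effects, the random-effect variance and residual error
(additive/proportional/combined). The PD model is fitted sequentially with
each subject's concentration function frozen at their post hoc PK
parameters.

## Worked example

```
$ dapapkpd generate --n 85 --seed 1 --out outputs
wrote outputs/cohort.csv ({'dose': 31054, 'pk_obs': 417, 'pd_obs': 499})

$ dapapkpd simulate --dose 5 --n 1000 --seed 7 --out outputs
baseline median 6.82%  ->  12-month median 6.61% (5-95%: 5.79-7.49) [MC SE 0.021]

$ dapapkpd simulate --dose 10 --n 1000 --seed 7 --out outputs
baseline median 6.82%  ->  12-month median 6.55% (5-95%: 5.72-7.44) [MC SE 0.021]
```

The generated cohort carries ~417 quantifiable trough concentrations and
~499 HbA1c values, the scale of the original dataset. The simulations say:
a virtual population starting at a median HbA1c of 6.8% ends the treatment
year at a median of about 6.6% on 5 mg and about 6.5% on 10 mg — the
higher dose buys roughly 0.06-0.1 percentage points because 10 mg already
operates near the model's maximal effect.

Fitting the generated cohort recovers the generating parameters:

```
$ dapapkpd fit-pk --data outputs/cohort.csv --out outputs
{"theta": {"theta_cl": 234.19, "power_WT": 0.32}, ...}
```

against generating values θ_CL = 229.3 L/day and θ_BW = 0.41.
`dapapkpd fit-pd` runs the sequential PD stage, `covsearch` the stepwise
covariate screen, `vpc` and `bootstrap` the qualification procedures.

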