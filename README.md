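# hepatokit

Compartmental and graphical analysis of hepatobiliary radiotracer kinetics
from dynamic imaging, for small-cohort transporter studies.

When an uptake transporter is knocked out (or inhibited), the change in a
drug's *hepatic uptake clearance* quantifies that transporter's contribution
to liver uptake. Dynamic imaging — PET for a ¹¹C-labelled drug, planar
scintigraphy for a ⁹⁹ᵐTc-labelled probe — yields time–activity curves (TACs)
for blood, liver and intestine, and a kinetic model turns those curves into
transfer parameters that can be compared between wild-type and knockout
groups. `hepatokit` implements that full analysis chain for researchers in
PK imaging: TAC handling, the dual-input three-compartment liver model,
integration-plot (graphical) uptake analysis, a synthetic-cohort generator,
and exact small-sample group statistics.

## The model

The liver receives tracer through the hepatic artery and the portal vein.
The arterial concentration C_A(t) is taken from the image-derived blood
curve; the portal concentration is not measured and is modelled as the
arterial curve passed through a single-compartment gut-transit system,

    C_PV(t) = k_pv ∫₀ᵗ C_A(s) e^(−k_pv (t−s)) ds,

a unit-gain kernel that delays and smooths the bolus while preserving total
exposure. The flow-weighted dual input is

    C_in(t) = f_HA · C_A(t) + (1 − f_HA) · C_PV(t),      f_HA = 0.17,

where f_HA is the hepatic arterial flow fraction. Tracer amounts in
hepatocytes (A_H) and excreted bile/intestine (A_B) follow

    dA_H/dt = CL₁ · C_in(t) − (k₂ + k₃) · A_H,      A_H(0) = 0
    dA_B/dt = k₃ · A_H,                              A_B(0) = 0

with CL₁ (mL/min) the hepatic uptake clearance, k₂ (min⁻¹) the
hepatocyte→blood backflux rate and k₃ (min⁻¹) the biliary excretion rate.
The observed liver signal is A_H/V_liver (PET, %ID/mL) or A_H itself
(planar count data); the intestinal signal is A_B. Fits are iteratively
reweighted nonlinear least squares jointly over the liver and intestine
curves, multi-started in log-parameter space, with asymptotic %CV per
parameter.

Around the model sit:

* **Integration plot** — OLS of X_t/C_t against AUC_blood(0–t)/C_t over an
  early window; the slope estimates the tissue uptake rate constant
  k_uptake and the intercept the initial distribution volume V_E.
* **Fraction transported** — f_t = (CL₁,wt − CL₁,ko)/CL₁,wt, the knocked-out
  transporter's share of total hepatic uptake clearance.
* **Exact Mann–Whitney U** — the null distribution is enumerated over all
  C(n_a+n_b, n_a) group assignments (mid-ranks for ties), as the normal
  approximation is unreliable at n = 4–5 per group.
* **Synthetic cohorts** — wild-type/knockout studies for both acquisition
  scenarios (20-frame/40-min PET; 54-frame planar) with log-normal
  between-animal variability and frame-duration-scaled multiplicative
  noise, carrying ground truth for recovery experiments.

## Worked example

Simulate a two-group PET study and run the full pipeline:

```
hepatokit simulate-cohort --scenario erlotinib --n-wt 5 --n-ko 4 --seed 1 --out study
hepatokit report --tacs study/tacs.csv
```

which prints (abridged):

```
Group summaries (mean +/- SD, n; %CV range where fitted):
  wild-type  cl1            8.061 +/- 3.012  (n=5)  (%CV 11.7-67.4)
  wild-type  k2             1.285 +/- 0.6713  (n=5)  (%CV 11.5-68.0)
  knockout   cl1            4.282 +/- 2.086  (n=4)  (%CV 7.1-80.5)
  knockout   k2             0.6123 +/- 0.5634  (n=4)  (%CV 6.9-81.7)

Group comparisons (exact Mann-Whitney U, two-sided):
  cl1            U=1.0  p=0.0317 *   1.9-fold
  k2             U=4.0  p=0.1905     2.1-fold

fraction transported f_t = 0.47
```

Each line of the summary is a group mean ± SD of a fitted parameter with
the range of per-fit %CV in parentheses; the comparison block gives the
exact U statistic, two-sided p (stars at p ≤ 0.05 / p ≤ 0.01) and the
wild-type/knockout fold-change of the group means. Here the simulated
knockout cohort shows the expected significant reduction in hepatic uptake
clearance (p = 0.032), and the f_t line estimates the knocked-out
transporter's share of liver uptake from the two CL₁ group means.

The same steps are available as library calls
(`hepatokit.generate_study`, `hepatokit.run_pipeline`, …) and piecemeal via
the `fit`, `integration-plot` and `compare-groups` subcommands.

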