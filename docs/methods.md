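# Methods

## Curve representation and sampling convention

A dynamic acquisition is a contiguous frame sequence; regional values are
frame averages of the underlying concentration. For analysis, each TAC's
values attach to frame *midtimes*; between midtimes the curve is linearly
interpolated, with value 0 at t = 0 (bolus i.v. injection) and constant
extrapolation after the last midtime. AUCs are trapezoid integrals of that
piecewise-linear curve, including the 0-at-origin ramp — exact for the
assumed shape and additive over time partitions.

All convolutions with exponential kernels (the portal transit system and
the hepatic compartment solution) are evaluated *in closed form per linear
segment* with a one-step recursion, so their only error is floating-point
round-off; the small-|x| branches of (1−e⁻ˣ)/x and (1−(1+x)e⁻ˣ)/x² use
series expansions to stay stable for rates or segments near zero.

## Dual-input function

The hepatic arterial flow fraction defaults to f_HA = 0.17 of total liver
blood flow. The portal curve is the arterial curve convolved with the
unit-gain gut-transit impulse response k_pv·e^(−k_pv t). The transit rate
k_pv is estimated jointly with the kinetic parameters by default (bounds
0.5–20 min⁻¹, initial 2 min⁻¹); a one-parameter transit model keeps the
portal estimation identifiable from liver data alone. Fixing k_pv
(`k_pv_mode: fixed`) is supported and substantially tightens CL₁ precision
when an independent transit estimate exists; joint estimation remains the
default because per-animal transit is rarely known.

Because the model is linear, the compartment solution for a
piecewise-linear arterial forcing reduces to two exponential convolutions
(rates k₂+k₃ and k_pv) combined through the kernel-composition identity;
the intestinal amount follows from the running integrals in closed form.
An independent LSODA ODE integration (rtol 1e-8, atol 1e-10) of the same
three-state system agrees with the closed form to ≤1e-6 relative and backs
arbitrary (non-piecewise-linear) forcing functions.

## Fitting

Per animal, CL₁, k₂, k₃ (and optionally k_pv) are fitted jointly to the
liver and intestine curves, with the blood TAC as forcing. The estimator is
bounded trust-region least squares in log-parameter space (bounds CL₁ ∈
[1e-4, 100] mL/min; k₂, k₃ ∈ [1e-5, 10] min⁻¹ — wide enough to span the
three orders of magnitude separating slow and fast tracers), multi-started
from 8 points (geometric mid-bounds plus 7 log-uniform draws, seeded).

Residual weighting follows the noise structure of frame-averaged count
data, SD ∝ value/√(frame duration): each frame gets weight √dt / value,
floored at 5% of the channel maximum so near-zero frames cannot dominate.
Weights start from the data and are refreshed once from the fitted model
(IRLS), removing the bias that noise-correlated weights would otherwise
introduce. Uniform per-channel weighting (values rescaled by the channel
maximum) was evaluated and discarded: on simulated PET cohorts it inflates
the CL₁–k₂ ridge enough to push median CL₁ recovery errors past 20%,
whereas the variance-matched weights keep the median within a few percent
for both scenarios.

Per-parameter %CV comes from the asymptotic covariance — the inverse
weighted Gauss–Newton Hessian scaled by the residual variance — mapped to
the natural scale by the delta method (for log-parameters, SD(log p) *is*
the CV). Parameters pinned at bounds, zero channels, and negative or
singular variance estimates are flagged, never silently repaired.

### Identifiability

The two tracer scenarios differ sharply. With slow kinetics and 54 frames
(mebrofenin-like), CL₁ is recovered to a few percent. With fast hepatic
equilibration (k₂ ≈ 1 min⁻¹, erlotinib-like), the liver curve reaches
quasi-equilibrium with the input within ~2 min, so CL₁ is informed only by
the earliest, noisiest frames and lies on a flat CL₁–k₂ likelihood ridge:
per-animal errors of ~20% at 10% measurement noise are intrinsic, not an
optimizer artifact (extra multi-starts find the same optimum, and the
profile objective at the true CL₁ is within ~2% of the optimum). The
reported per-fit %CV ranges reflect exactly this pattern. Consequently,
cohort-level medians — not single fits — are the meaningful recovery
targets for the fast-tracer scenario.

## Integration plot

Ordinary least squares of y = X_t/C_t on x = AUC_blood(0–t)/C_t over an
early window; slope = k_uptake, intercept = V_E. The default window takes
all frames with midtime ≤ 5 min (deterministic); an adaptive policy takes
the longest initial run (≥4 points) keeping r² ≥ 0.95. The slope
approaches CL₁/V_liver only in the near-irreversible early-time limit;
backflux (k₂+k₃) and the portal transit lag both bias it downward, and on
model-generated curves the bias grows monotonically as the window extends
— at fast-equilibration parameters the 0–5 min slope can sit several-fold
below CL₁/V_liver. The statistic is therefore used comparatively (group
differences), not as an absolute clearance estimate.

## Cohort statistics

Group summaries use the sample (n−1) SD. Groups are compared with the
exact Mann–Whitney U test: mid-ranks for ties, full enumeration of all
C(n_a+n_b, n_a) assignments (guarded to n ≤ 12 per group), two-sided p as
twice the smaller tail probability capped at 1. At n = 5 vs 4 the smallest
attainable two-sided p is 2/126 ≈ 0.016 and the test is conservative
(empirical size ≈ 0.048 at α = 0.05). No multiple-testing correction is
applied across parameters. Fold-changes are ratios of group means;
fraction transported f_t = (CL₁,wt − CL₁,ko)/CL₁,wt is reported unclipped
with a warning if negative.

## Synthetic studies

The generator emulates the two study arms: a 20-frame/40-min PET scenario
(blood/liver in %ID/mL, intestine in %ID) and a 54-frame/38-min planar
scenario (blood in cps/mL via a body-weight-proportional heart volume,
default 5 µL/g; liver and intestine in cps, where CL₁ absorbs the
cps-vs-cps/mL calibration). Defaults: n = 5 wild-type vs 4 knockout;
group kinetic means and between-animal CVs set to the study's reported
values per tracer; parameters drawn independently log-normal (true
between-animal correlations are unknown — a stated limitation); arterial
input a tri-exponential bolus peaking before 1 min at %ID/mL scale
(amplitudes 15/4/1, rates 3/0.4/0.02 min⁻¹, rise 20 min⁻¹, scaled ×2000
for count-rate units); portal transit truth k_pv = 2 min⁻¹; liver volume
1.5 mL; body weight ~N(31, 4) g.

Measured blood values are frame averages of the continuous bolus model
(5-point Gauss rule per frame, like all frame averaging here). The liver
and intestine compartments are then driven by the same midtime
piecewise-linear reconstruction of those blood samples that the fitter
uses, so a zero-noise study is an exact self-consistency case and
estimation error comes only from injected measurement noise — the
generator deliberately does not model the input-reconstruction
discrepancy, partial-volume or spill-over effects of real imaging, so
passing recovery tests bound estimation error, not image-quantification
error. Noise is multiplicative Gaussian with SD = f/√(frame duration)
(default f = 0.10), mimicking count-limited frames; negatives are clipped
to zero and counted. Every record carries its ground-truth parameters.

## Problem sizes and determinism

Recovery experiments use 20 single-animal replicates per scenario at the
reference kinetics, reporting the median fitted CL₁; calibration checks on
the exact test use enumerated cohorts of drawn parameters (100 replicates
for power, 2000 for empirical size). Every stochastic routine takes an
explicit seed; CLI outputs embed the config digest (which includes the fit
seed), and regenerating a study from the same seed is byte-identical.

## Known limitations

* No vascular (blood-volume) fraction in the liver signal and no
  enterohepatic recirculation; intestinal activity is treated purely as
  excreted bile.
* Input TACs are assumed decay-corrected; no decay term is modelled.
* The portal transit model is a single exponential kernel; dispersed or
  delayed variants are not implemented.
* The integration-plot window is a fixed early interval by default; no
  per-tissue window optimization.
* Exact Mann–Whitney is limited to ≤12 animals per group by enumeration.
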