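# Methods

## Model

The package implements a two-subclone cell-quota model of prostate tumor
dynamics under intermittent androgen suppression (IAS). State variables:
castration-sensitive volume `x1` [L], castration-resistant volume `x2` [L],
cell quota `Q` [nmol] (bound androgen receptors per unit biomass), serum
androgen `A` [nmol/L, written nmol below] and serum PSA `P` [ug/L].

Assumptions baked into the equations:

* **Droop growth.** Each subclone proliferates at `mu (1 - q_i/Q)`, floored
  at zero: below its minimum cell quota a clone neither grows nor (under
  the default PSA law) secretes PSA. `q2 < q1` defines resistance — the
  resistant clone tolerates lower androgen.
* **Competition, no cost of resistance.** A shared density-dependent death
  term `d x_i (x1 + x2)` models competition for non-androgen resources.
  Without treatment the tumor still drifts towards resistance via the
  one-way transformation flux `c K/(Q+K) x1` (no back-transformation).
* **Androgen feedback.** Testicular production `gamma1 u(t) (1 - A/A0)`
  is a negative feedback loop around the homeostatic level `A0`, switched
  off (`u = 0`) during androgen deprivation; adrenal production `gamma2`
  persists. The quota relaxes towards serum androgen at rate `m` minus the
  amount consumed by proliferation (population-weighted; defined as 0 for a
  vanishing population).
* **Proliferation-coupled PSA.** `dP/dt = bQ + sum_i max{sigma_i
  (1 - q_i/Q) x_i, 0} - eps P`. The alternative classical law, secretion
  linear in volume (`bQ + sigma1 x1 + sigma2 x2 - eps P`), is retained as
  `psa_law="linear"`; the clinical head-to-head comparison of the two laws
  is out of scope here.

Time is in days. Units follow the parameter table as printed in the
source literature, including its dimensional idiosyncrasies; we do not
"repair" them. Treatment schedules are ordered half-open `[start, end)`
intervals; a switch day belongs to the interval it starts.

### Parameters

| symbol | meaning | unit | bounds (calibration) | default |
| --- | --- | --- | --- | --- |
| mu | max proliferation rate | 1/d | 0.001–0.09 | 0.04 |
| q1 | CS minimum cell quota | nmol | 0.41–1.73 | 0.6 |
| q2 | CR minimum cell quota | nmol | 0.01–0.41 | 0.2 |
| d | density death rate | 1/(L·d) | 0.001–0.30 | 0.02 |
| c | max transformation rate | 1/d | fixed 1.5e-4 | — |
| K | transformation half-saturation | nmol | fixed 1 | — |
| gamma1 | testicular androgen production | nmol/d | 0.008–0.8 | 0.2 |
| gamma2 | adrenal androgen production | nmol/d | fixed 0.005 | — |
| A0 | homeostatic serum androgen | nmol | patient max androgen ±10 | 20 |
| delta | androgen degradation | 1/d | 0.03–0.15 | 0.08 |
| m | quota diffusion rate | 1/d | fixed (not estimated) | 0.9 |
| b | baseline PSA production | ug/(nmol·d) | 1e-4–0.1 | 0.001 |
| sigma1, sigma2 | max PSA production | ug/(nmol·L·d) | 0.001–1 | 0.2 |
| eps | PSA clearance | 1/d | 1e-4–0.1 | 0.05 |

`m` has no published range; it is fixed at 0.9/day (quota equilibrates
with serum androgen within days, much faster than tumor turnover) and
exposed in configuration but never estimated — the calibration deliberately
caps the number of free parameters for identifiability.

## Numerics

* **Public simulation** (`iasmark.model.simulate`) uses `scipy`'s adaptive
  RK45 at rtol 1e-8 / atol 1e-10, restarted at every treatment switch so
  the discontinuous input is honored exactly. States are clamped
  non-negative; the quota is floored at 1e-9 nmol and trajectories that
  touch the floor are flagged. LSODA is avoided: the `max{}` gates make the
  right-hand side non-smooth and its stiffness detection misfires.
* **Calibration-loop simulation** uses a numba-jitted fixed-step RK4 at
  dt = 0.5 day. At the model's time scales (fastest rate ~1/day) the
  discretisation error is far below observation noise, the cost is
  microseconds per segment, and — unlike adaptive stepping — the objective
  surface carries no step-size-control noise, which matters for the
  trust-region optimizer.

## Calibration protocol

Fitting is per patient, in two phases, mirroring segment-wise clinical
calibration practice for this model family:

1. **Test run.** The castration-sensitive-side parameters
   `{mu, q1, d, gamma1, delta, b, sigma1, eps}` are fitted jointly over the
   patient's first two on/off cycles and then frozen. `q2` and `sigma2` are
   excluded: the resistant clone is a ~1% fraction early on, so these are
   unidentifiable there (in practice they pin at bounds). `sigma2` is
   initialised at the fitted `sigma1` (the resistant clone arises from the
   sensitive one and shares its secretion machinery); `A0` is set to the
   patient's maximum recorded androgen. The pre-treatment initial state
   sets `A(0) = Q(0)` to the first recorded androgen, `P(0)` to the first
   PSA, and tumor volume (`x2 = 0.01 x1`) from the PSA production balance
   at the candidate parameters, so the convention is re-derived per
   objective evaluation during this phase.
2. **Per-segment fits.** The four key parameters `{mu, q2, d, sigma2}` —
   resistant growth, resistance level, competition, resistant secretion —
   are re-estimated on every treatment segment in order. Each segment's
   initial state is the previous segment's terminal simulated state
   propagated to the segment's first observation day; each segment's
   parameter values start from the previous segment's estimates. `q2` is
   re-estimated only on **on-treatment** segments and carried unchanged
   through off-treatment segments: off treatment the quota sits at serum
   levels (several nmol), an order of magnitude above the entire admissible
   q2 range, so off-treatment data contain essentially no information about
   q2 and estimating it there only injects noise into the biomarker.

**Objective.** Weighted least squares with 80% weight on PSA and 20% on
androgen, each channel's error averaged over its non-missing observations
(weights renormalise if a channel is absent). The default residual is the
log-ratio `log((sim + 0.1)/(obs + 0.1))`: serum PSA and testosterone errors
are multiplicative, and the castrate-range PSA tail — where `b`, `q2` and
`sigma2` are identified — would be invisible under amplitude
normalisation. The additive offset (0.1 in channel units) bounds the
influence of near-zero readings. A segment-mean-normalised squared-error
variant (`error_norm="segment_mean"`) is available. Simulated androgen is
clipped at the assay detection floor (0.7 nmol/L) before residuals, the
standard treatment of left-censored castrate measurements.

**Optimisation.** Bounded trust-region least squares (`scipy
least_squares`, method `trf`) in log10 parameter space (bounds span up to
three decades), multi-start: the warm start (previous segment's values),
the configured defaults, the bounds midpoint, and seeded uniform draws, 8
starts per segment by default. A restart displaces the incumbent only if
it improves the objective by at least 25% relatively
(`start_accept_margin`): in directions the segment does not identify, the
objective is nearly flat and an unconstrained "best of N" would follow
noise; the margin makes parameter continuity across segments the tie-break
while still letting genuinely demanded regime changes (e.g. resistance
emerging, with order-of-magnitude objective drops) through. All randomness
derives from a single seed plus a stable per-patient hash.

## Biomarkers and classification

* **q2 ratio** = q2(first segment)/q2(last segment); rises above 1 as
  resistance evolves; `q2_trend` gives the running version. Orientation is
  fixed so that "exceeds threshold ⇒ failure".
* **Androgen/PSA ratio** = mean androgen / mean PSA over a window: the
  first 200 days of the record ("early", a negative control) or the final
  on-treatment segment truncated to its *first* 200 days ("final" — the
  resistance signal emerges during suppression; a last-200-days variant is
  a one-line configuration change). Patients without androgen data are
  excluded, not imputed. Ratios above 5 are capped at 5 in plots only.
* **Thresholds.** "Max" scans the midpoints of consecutive sorted unique
  values plus the unbounded extremes — accuracy is piecewise constant, so
  this search is exact — breaking ties towards the midpoint of the widest
  optimal interval (stability under perturbation). "SVM" is a linear
  soft-margin SVM (C = 1) on the standardised 1-D feature, boundary mapped
  back to the original scale. Failure is the positive class throughout.
* **Cross-validation.** Stratified 5-fold, threshold refit on each training
  split, shuffled and replicated (default 100×), fully seeded.
  Stratification (rather than plain shuffling) prevents class-empty folds
  at the default 51/20 composition.

## The virtual cohort

The generator emulates the data structure of a ~71-patient IAS trial with
two archetypes drawn from the same parameter distributions (uniform inside
the calibration bounds, narrowed to dynamically sensible sub-ranges that
yield serum-like scales: off-treatment androgen ~6–12 nmol/L, relapse PSA
above 10 ug/L, multi-cycle records within a 2000-day horizon):

* **responder** — constant q2; PSA and androgen cycle concordantly;
* **resistant** — q2 multiplied by a factor rho ∈ [0.5, 0.7] at every
  on→off transition (selection acts during suppression), floored at 0.01.
  Applying the decline at cycle boundaries keeps the hidden truth directly
  comparable to the one-q2-per-segment calibration output.

Treatment follows a PSA-triggered protocol: ADT stops once PSA has stayed
below 4 ug/L for 14 days (not before 240 days on treatment), resumes when
PSA exceeds 10 ug/L (not before 75 days off), and the record ends at the
horizon — or on treatment, as a resistance-driven trial exit, when an
on-phase fails to reach remission within 540 days. The published trial's
exact protocol is not public; these rules are a modelling choice, not a
claim about that trial. Visits occur every 28 ± 7 days (minimum 7);
observations are the noise-free trajectory under multiplicative lognormal
noise (CV 10% PSA, 15% androgen) with androgen left-censored at
0.7 nmol/L. Labels are the archetype (resistant = failure, matching
"discontinuation due to resistance" outcomes); the default composition,
51 failures/20 successes at n = 71, is the unique integer split consistent
with the published accuracy/sensitivity/specificity triple at that cohort
size.

What the generator does **not** emulate: between-assay site effects,
dropout and informative censoring, comorbidity-driven outcome labels,
PSA kinetics unrelated to the model (e.g. prostatitis spikes), or
model-misspecification — virtual patients are draws from the fitted model
family itself. Passing end-to-end tests therefore demonstrates that the
pipeline recovers planted resistance signals through realistic sampling
and noise, not that the published clinical accuracies transfer to new
cohorts.

## Problem sizes

Default experiment sizes were chosen to make the full suite and the
acceptance run comfortably desktop-scale: solver fidelity on 20 bounded
parameter draws over 40-day windows against a dt = 0.001 RK4 reference;
parameter recovery on 20 noise-free plus 20 noisy (5% CV) virtual
patients; threshold optimality on 50 random 1-D datasets; the end-to-end
pipeline on one 71-patient cohort with 20 CV replicates. The cohort
calibration is the dominant cost (~2 minutes on one CPU).

## Known limitations

* The q2 ratio's numerator (first-segment q2) is weakly identified while
  the resistant clone is still rare; the warm-start continuity prior
  stabilises it, but individual responders can still show ratios far from
  1 (both directions). Classification accuracy rests on the cohort-level
  separation, not on per-patient ratio precision.
* The SVM threshold can degenerate on heavy-tailed, imbalanced biomarkers
  (the q2 ratio): the standardised boundary leaves the data range and the
  rule predicts the majority class. The Max threshold has no such failure
  mode and is the default.
* Off-treatment segments inherit q2 rather than estimating it; a trial
  design with informative off-treatment androgen kinetics would require
  revisiting that choice.
* Phase-1 fixed parameters absorb identifiability trade-offs (e.g.
  gamma1/A0 compensation); their absolute values should not be
  over-interpreted even when the fit is good.
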