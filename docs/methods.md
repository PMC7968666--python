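# Methods

## Study setting and model

The package analyses destructive-sampling pharmacokinetic studies in
mosquitoes: each individual is sacrificed at a single nominal time after a
drug-containing blood meal and contributes one whole-body amount (ng).
With one observation per individual, population (mixed-effects) modelling
is the only way to separate between-mosquito variability from residual
error.

The structural model is a one-compartment whole-body curve with an initial
lag phase and zero-order elimination: the amount stays at the absorbed dose
D until T_lag, then declines linearly at rate k_el and is clipped at
exactly zero (amounts are physical quantities).  First-order and
Michaelis–Menten elimination are implemented alongside for model
comparison; the Michaelis–Menten inverse is solved by bisection on the
monotone implicit time solution, and its AUC to infinity has the closed
form (Km·D + D²/2)/Vmax.

Individual parameters combine fixed effects, allometric weight scaling to
a 3.4 mg reference (exponent 1 on amounts, 0.75 on rates — the standard
convention when no exponent is estimated), lognormal inter-individual
variability on dose and elimination rate, a feeding-occasion random effect
on dose (each mosquito feeds exactly once, so the occasion is the feeding
batch), and an additive lag extension in ritonavir co-treatment arms.
Residual error is combined proportional + additive on the amount scale,
with the variance evaluated at the individual prediction (eta–epsilon
interaction).  Variability magnitudes are interpreted as standard
deviations; a `variance_parameterization` flag provides the variance
reading.

Default parameter values are the package's reference scenario for
ivermectin in *Ae. aegypti*: absorbed dose 0.28 ng, elimination 5.5 pg/h,
lag 18.5 h, +11.4 h lag under ritonavir, omega_dose 0.075, omega_kel 0.25,
occasion SD 0.11, sigma_prop 0.02, sigma_add 0.018 ng, LLOQ 0.005 ng.

## Below-LLOQ handling

Measurements below the lower limit of quantification are censored.  Three
treatments are available:

* `conditional` (default): censored records are excluded and every retained
  record's density is divided by P(y > LLOQ | eta) — the truncated-Gaussian
  (M2) likelihood.  Plain exclusion is biased here because censoring is
  informative: at late times the censored mosquitoes are exactly the ones
  near full depletion, and keeping only the upper tail flattens the
  apparent decline.  In full-design recovery experiments the plain-drop
  estimator showed a ~9% downward bias in k_el, which the conditional
  likelihood removes.  Because predictions are non-negative, the truncation
  argument is bounded below and the correction is numerically benign.
* `drop` (M1): plain exclusion; appropriate (and faster) for designs whose
  observation window ends before substantial depletion.
* `censored` (M3): censored records kept with a Gaussian-CDF contribution.

## Marginal likelihood

The OFV is −2 log of the likelihood marginalised over all random effects,
computed by a nested approximation, vectorised across records:

1. **Per record**, the 2-d integral over (eta_D, eta_k) given the batch
   deviate splits at the zero-amount clip.  Over the fully-depleted
   half-plane {omega_D·eta_D − omega_k·eta_k ≤ beta} the observation factor
   is constant, so that part is **exact**: the residual density at zero
   amount times a Gaussian half-plane mass.  The on-curve part is a Laplace
   term at the interior conditional mode — located by damped Newton with an
   analytic gradient and Hessian, started from an analytic point where the
   dose deviate reproduces the observation — multiplied by the Gaussian
   mass of the mode's own half-plane in the Hessian metric.  This smooth
   truncation factor vanishes as the mode slides into the depleted region,
   so the two parts never double-count.  Records whose on-curve optimum
   sits exactly on the depletion boundary (a one-sided stationary point
   Newton cannot satisfy) are snapped to the analytic boundary optimum,
   evaluated from the curve side for continuity.
2. **Per batch**, the occasion deviate is integrated by a 1-d Laplace step
   around the minimum of h(kappa) = kappa²/2 + log(2π)/2 − Σ log I_i(kappa),
   found by a safeguarded Newton iteration with a deliberately wide
   (1e-2) finite-difference step: h is evaluated through iterative inner
   refinements with a ~1e-8 noise floor and log h'' enters the OFV, so the
   curvature must average over that noise.

A conventional single-mode joint Laplace was tried first and abandoned: the
clip makes the conditional density of late-time records bimodal, and basin
flips made the OFV discontinuous in the population parameters, which broke
the outer quasi-Newton search.  The nested dual-region form is smooth,
deterministic (all mode searches start from analytic candidates) and agrees
with 32-node adaptive Gauss–Hermite quadrature to well under 0.1 OFV units
on small instances whose curves stay clear of full depletion inside the
sampling window; agreement in the fully-depleted regime is not claimed —
the likelihood is genuinely non-smooth there and no Laplace-type
approximation (by any implementation) is accurate at a kinked mode.

Several parameter vectors are evaluated in one stacked vector pass
(`neg2ll_multi`), which makes a full finite-difference gradient cost only a
small multiple of a single evaluation.

## Estimation

`fit` minimises the OFV with chained L-BFGS-B runs over rescaled
log-transformed parameters (lag times on a bounded linear scale).  Details
that matter:

* forward-difference gradients, relative step 1e-4, all stencil points in
  one stacked evaluation;
* per-parameter rescaling by typical curvature, which brings the search to
  near-unit conditioning and cuts iteration counts several-fold;
* restarting L-BFGS-B (clearing its curvature memory) until the OFV stops
  improving — on this mildly kinked surface the line search often gives up
  early, and a fresh start reliably makes further progress; a chain that
  stops improving is treated as converged even when the last line search
  ends abnormally;
* staged start: with no user initial values, the fixed effects are fitted
  first with the variability magnitudes frozen at data-driven guesses
  (dose from the mean amount at the first sampling time, elimination rate
  from dose over the observation span, lag from the first time bin whose
  mean drops below 90% of the dose), then everything is released;
* jittered restarts only when the chain fails — unconditional restarts
  would multiply every fit's cost for no benefit on these surfaces;
* a fit whose estimated lag exceeds every sampling time is flagged
  non-identifiable (no post-lag information reaches the elimination rate).

Standard errors come from the inverse numerical Hessian of OFV/2 on the
natural scale with wide (1e-2 relative) steps — the OFV carries a ~1e-3
evaluation noise floor and log-curvatures span 1e3–1e5, so narrow stencils
drown in noise.  %RSE = 100·SE/estimate.

## Bootstrap, VPC, CWRES

The non-parametric bootstrap resamples mosquitoes with replacement,
stratified by batch × arm × nominal time by default (preserving the design
shape) with plain resampling by flag; each replicate is refitted from the
original estimates with a reduced iteration budget.  A replicate fails on
non-convergence or a fixed effect pinned at a search limit; a variability
magnitude shrinking to its lower bound is a legitimate zero estimate, not a
failure (otherwise a dataset whose realised occasion spread happens to be
tiny fails every replicate).  Replicate Hessians are not computed (cost),
so the positive-definiteness check applies only to the base fit.  More than
50% failures aborts.  Note that stratified resampling within small cells
deflates bootstrap variance by roughly (n−1)/n per cell; calibration
experiments on small designs should use plain resampling.

The VPC simulates the fitted model under the original design and compares
observed 5th/50th/95th amount percentiles per nominal time bin with 90%
prediction bands across simulations.  CWRES are computed from the
linearisation of the model about the conditional random-effect modes
(including the batch deviate in the covariance) and are approximately
standard normal under the true model; on simulated-at-truth data the
empirical mean sits within ±0.05 and the SD within a few percent of 1.

## Synthetic-data generator

The generator reproduces the study design exactly: four feeding occasions,
each pairing an ivermectin-alone arm with one combination arm
(ketoconazole / rifampicin / ritonavir / piperonyl butoxide), sampling at
0/6/12/24/36/48/72 h with 20 mosquitoes per cell (1120 records), occasion
deviates shared within batch, and LLOQ censoring applied to the simulated
measurement.  Censoring concentrates almost entirely at 72 h, where the
reference curve (depletion at ~69 h) has reached zero for over half of the
population.

Body weight is modelled compositionally: an unfed mass (lognormal, median
0.9 mg, CV 15%) plus the imbibed meal mass — meal volume lognormal with
mean 3.6 µl and CV 16.7% (matching a 0.36 ± 0.06 ng uptake at 0.1 µg/ml)
times a blood density of 1.06 mg/µl — with the meal fraction digested
linearly, 64% gone by 72 h.  These defaults give a mean post-feeding weight
near 4.6 mg, a pooled median recorded weight of ~3.5–3.8 mg (slightly above
the 3.4 mg reference: a linear digestion model cannot reproduce both the
post-feeding mean and the pooled median exactly, and the covariate model is
self-consistent either way), and ~52% total weight loss over 72 h.  The
compositional form couples weight to meal size, which is what makes
weight-normalisation genuinely reduce dosing CV — with an independent
weight model, normalising would *add* variability.  An independently drawn
weight model misses any correlation between imbibed volume and unfed body
size; within-cell volume–weight correlation beyond the compositional link
is not modelled.

The linearity generator produces amount = concentration × volume with an
8% proportional assay error (a typical intra-run precision bound), giving
raw per-concentration CVs in the high teens and weight-normalised CVs of
7–13%.  A consequence worth knowing: over the 0.01–1 µg/ml range an ~18%
proportional scatter caps the per-mosquito raw-amount regression R² near
0.95; R² ≈ 0.99 is reached on weight-normalised amounts, and
`dosing_linearity` reports either.

The endpoint generator draws daily-survival binomial chains (monotone by
construction) from a four-day survival probability per arm, negative
binomial egg counts and binomial hatching.  Default rates encode the
reference scenario: 92% control survival, 10–17% four-day mortality for the
single drugs, 42% mortality for ivermectin + ritonavir, near-zero hatching
in every ivermectin arm.

What passing tests on these synthetic data do *not* show about real data:
the generator assumes the fitted model's own structure (no model
misspecification), linear blood-meal digestion, independent lognormal
weights and volumes, and a Gaussian assay error; none of the rearing,
feeding-behaviour or extraction-recovery complications of a live experiment
are represented.

## Recovery experiments

`parameter_recovery` simulates full-design studies at the reference
parameters and refits them; the headline summary is the per-parameter
median over five seeds, which falls inside the reference CI90 for all four
fixed effects (dose 0.277–0.283 ng, k_el 5.1–5.9 pg/h, T_lag 17.0–19.8 h,
ritonavir lag 8.7–14.2 h).  The occasion deviates are drawn centred
(sample mean zero across the four batches): with only four occasions the
population dose is identified only jointly with the mean realised occasion
effect — an irreducible ~omega_IOV/√4 ≈ 5.5% scatter per dataset — whereas
a CI90 of ±1% on dose is conditional on the realised occasions (a bootstrap
that resamples mosquitoes within batches holds the occasion effects fixed).
Centring removes exactly that confounded component so the experiment tests
the fixed effects themselves.  The pipeline and simulator default remains
uncentred i.i.d. N(0,1).

The bootstrap calibration experiment uses a reduced mono-arm design
(4 batches × 6 sampling times up to 48 h × 3–4 mosquitoes per cell): the
window ends before substantial depletion, so LLOQ censoring is negligible
and the plain-exclusion likelihood is unbiased there; plain resampling
avoids the small-cell variance deflation noted above.  Two repeated runs of
200 replicates each are used — sized for routine test runtimes on one CPU —
and both CI90s must cover the generating elimination rate.

## Known limitations

* The Laplace-type OFV is an approximation; its accuracy degrades for
  records pinned at the depletion boundary (kinked conditional modes), and
  log h'' contributes an evaluation noise floor of ~1e-3 OFV units.
* Standard errors are unavailable when the numerical Hessian is not
  positive definite, which happens routinely on small designs when a
  variability magnitude collapses toward zero.
* The occasion effect enters dose only; four occasions give very little
  information about omega_IOV, whose estimate frequently hits zero on
  reduced designs.
* No time-to-event analysis of the mortality data (day-wise percent
  survival only), no egg-mass-to-count calibration, and no modelling of the
  co-administered compounds' own kinetics beyond the structural curve
  shapes provided for plotting and comparison.
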