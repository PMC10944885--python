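# Methods

`poppk` implements a complete population-pharmacokinetic (PopPK) analysis
of oral ORIN1001, an IRE1-α endoribonuclease inhibitor studied in a phase-I
dose-escalation trial in patients with advanced solid tumors. Because the
patient-level data are confidential, the package pairs the published final
model with a synthetic-trial generator that emulates the study design, so
every stage — estimation, covariate selection, diagnostics, simulation —
is exercised end to end on data with the assumed statistical structure.

## Structural model

Disposition is a linear two-compartment model; absorption is first order
after a lag. For a dose *D* (mg) at time *t_d*, the central concentration
at *t' = t − t_d − Tlag > 0* is the tri-exponential

    C(t') = 1000 · D · Ka / V · [ A e^{−αt'} + B e^{−βt'} + C e^{−Ka·t'} ]

with micro constants k10 = CL/V, k12 = CL2/V, k21 = CL2/V2, macro
constants α, β from α+β = k10+k12+k21, αβ = k10·k21, and the standard
coefficients A, B, C. All parameters are apparent (bioavailability F is
absorbed: V/F, CL/F, ...), mirroring how an oral-only study reports them.
Multiple doses superpose exactly; steady state under interval τ follows by
summing each exponential's geometric series. The closed form is the primary
path (it is what the FOCE inner loop and the Monte Carlo harness evaluate,
thousands of times per fit); a high-accuracy ODE integration of the
three-state system exists only as a test oracle, and the two agree to
relative 1e-6 over random parameter draws.

Numerical choices: when Ka collides with a disposition constant (a
removable singularity of the closed form) Ka is perturbed by 1e-8
relative; the steady-state peak is located on a 0.05 h grid and refined by
golden-section search (no closed form exists for the peak time with lag);
AUC_ss is computed as Dose/CL, exact for a linear model.

## Hierarchical model

Individual parameters follow the lognormal exponential-IIV model
P_ij = TVP_i · exp(η_ij), η ~ N(0, ω²), with IIV on V/F, CL/F, Ka and
Tlag (a configuration flag allows IIV elsewhere during base-model search,
and a correlation matrix turns on a non-diagonal omega; the packaged final
model is diagonal). Continuous covariates act as power functions
normalised at the cohort median, (cov/median)^θ. Residual error is
proportional by default (SD = stdev0 · prediction), with additive and
combined variants for the base-model search.

The packaged final model (`poppk.final_model()`):

| parameter | value | | parameter | value |
|---|---|---|---|---|
| Ka | 0.58 1/h | | θ TBIL→CL/F | −0.46 |
| Tlag | 0.35 h | | θ LBW→CL/F | 1.11 |
| V/F | 26.21 L | | θ LDH→V2/F | 0.99 |
| V2/F | 26.60 L | | θ LBW→CL2/F | 2.21 |
| CL/F | 1.07 L/h | | ω² (V, CL, Ka, Tlag) | 0.049, 0.067, 0.534, 0.438 |
| CL2/F | 0.75 L/h | | stdev0 | 0.197 |

Reference medians: TBIL 10.30 μmol/L, LBW 45.13 kg, LDH 214 IU/L.

Derived covariates use the standard formulas: BMI; DuBois BSA;
Janmahasatian LBW; Devine IBW; Deurenberg body-fat %; Cockcroft-Gault
CLcr (creatinine converted to mg/dL); adjusted weight
IBW + 0.4·(wt − IBW) only when BMI > 25, and adjusted CLcr from it. They
sit behind one switchboard (`poppk.covariates.derive_covariates`) so an
alternative formula set can be swapped in one place.

## Estimation

The objective is −2× the FOCE-with-interaction approximation of the
marginal log-likelihood. Per subject, the inner problem finds the
conditional mode of η by Newton iterations with the exact gradient of the
penalised criterion and a Gauss-Newton Hessian (2 JᵀV⁻¹J + 2Ω⁻¹), with
backtracking line search and warm starts across outer iterations; the
residual variance is evaluated at the conditional (individual) prediction
— the "interaction" flavour. The subject's contribution is

    OFV_j = Σ_i [r_i²/v_i + ln v_i] + η*ᵀΩ⁻¹η* + n_j ln 2π + ln|Ω|
            + ln|JᵀV⁻¹J + Ω⁻¹|

The outer search runs L-BFGS-B on log typical values, raw covariate
exponents, log ω² (or a log-diagonal Cholesky factor when omega is
non-diagonal) and log residual SD, so positivity needs no bounds. A lag
time crossing an observation time makes a subject's inner problem
multi-modal, so the FOCE surface carries small discontinuities where the
conditional mode jumps basins; the outer search therefore uses a coarse
finite-difference step (3e-3 on the log scale, large enough that real OFV
differences dominate the basin jumps) and, between L-BFGS-B rounds, probes
each coordinate at ±0.05 and ±0.25 for a lower basin to restart from (up
to three rounds). Convergence within a round: relative OFV change below
1e-9 with a projected-gradient tolerance of 1e-3, at most 500 iterations;
non-convergence is reported on the results object, never silently.
Standard errors come from the numerical Hessian of the OFV
(cov = 2H⁻¹, delta method back to the reporting scale); RSE% for variance
components is reported on the variance scale. Starting values default to
NCA-informed heuristics (CL from median dose/AUC, V from median
dose/Cmax, exponents at zero).

Two numerical safeguards: η excursions during line search are clipped at
±40 before exponentiation, and predictions are floored at 0.5 ng/mL (1% of
the assay LLOQ) inside the proportional-error variance so that a lag-time
excursion past an observation time cannot create a zero variance. A
non-PSD or numerically singular omega proposal is rejected with a finite
penalty rather than an exception.

The honest check on the approximation is the quadrature oracle: on one-
and two-η toy problems the FOCE OFV agrees with adaptive/Gauss-Hermite
integration of the exact marginal likelihood to well under 0.5%.

## Covariate selection

A Pearson pre-screen excludes one member of every covariate pair with
|r| > 0.5 and p < 0.05; within a collinear pair the retained member is the
one with the larger univariate OFV drop when tested alone on CL/F
(caller-supplied ranking), with a fixed cohort-table priority as the tie
break — the selection criterion inside the pre-screen is this package's
choice, since only the threshold is externally fixed. Survivors enter
forward inclusion (add the best parameter–covariate pair while ΔOFV >
3.84, the χ²₁ 0.05 quantile) over CL/F, V/F, CL2/F and V2/F, then backward
elimination (delete while the OFV rise is ≤ 6.64, the χ²₁ 0.01 quantile).
Sex is excluded from power-form screening: a power of a median is
meaningless for a binary covariate.

## Diagnostics

CWRES uses the FOCE linearisation: the model-implied covariance
V = JΩJᵀ + R(η*) at the conditional mode decorrelates the linearised
residual y − f(η*) + Jη*. VPC and NPDE share one simulation harness
(replicates at the observed design: same doses, times and covariates,
fresh η and ε). VPC bins on the nominal sampling times (the design is
nominal-time sparse sampling), is uncorrected (no prediction correction),
and supports the three views used in practice: time after dose, the 0–96 h
induction window and the 576–600 h day-21 window. NPDE decorrelates
observed and simulated vectors with the simulated ensemble's mean and
Cholesky factor, converts ranks to probabilities clipped to
[1/2n, 1 − 1/2n], and maps through the normal quantile; summaries are the
t-test of mean 0, a χ² variance test against 1 and Shapiro-Wilk
normality. The bootstrap resamples subjects with replacement, stratified
by dose arm (arm sizes of 2–5 make unstratified resamples degenerate; the
flag is recorded in the output), refits, and reports percentile CIs with
failures logged and excluded.

Default replicate counts are 1000 (bootstrap, VPC, NPDE) and 500 virtual
patients per simulation scenario (`RunConfig`).

## NCA and dose proportionality

Per-profile NCA: Cmax/Tmax from the observed points, linear-up/log-down
trapezoidal AUC, λz by log-linear regression over the best adjusted-r²
tail of 3–6 points excluding Tmax (a common convention; the choice rule
is this package's), and the derived t½, AUC0-inf, CL/F, Vz/F. When the
tail is not credible (r² < 0.8 or < 3 points) the extrapolated quantities
are withheld rather than guessed. Dose proportionality is the Pearson
correlation of per-arm mean exposure against dose, reported to two
decimals, with a log-log variant alongside.

## Exposure simulation

Scenarios fix covariates at chosen percentiles (unset covariates stay at
the reference medians); each virtual patient gets fresh IIV draws and
closed-form steady-state metrics (Cmin,ss as the concentration τ after a
dose, Cmax,ss, AUC_ss) at the scenario dose — residual (assay) error is
excluded because exposure is a property of the individual's kinetics.
Fold change is the ratio of scenario mean to reference mean with a
nonparametric bootstrap CI over virtual patients (a mean-of-pairwise-
ratios estimator is available behind a flag); changes inside 80–125% are
flagged not clinically significant. Scenario and reference cohorts
simulated with the same seed share their η draws (common random numbers),
so the ratio of means is nearly free of Monte Carlo noise and converges to
the typical-patient ratio — the estimator's own invariant.

## Synthetic-trial generator

The generator emulates the study design: 25 subjects over seven
once-daily arms (100/200/300/400/500/650/900 mg with arm sizes
3/3/4/3/3/5/4), one dose at t=0 observed through 96 h, then 21 daily doses
from 96 h to 576 h, sampling at 0, 1, 2, 4, 6, 8, 12, 24, 48, 72, 96 h
post first dose and 0, 1, 2, 4, 6, 8, 12, 24 h after the 576 h dose — 19
nominal samples per subject, 475 records, with a dropout knob defaulting
to 4/475 so the default dataset has 471 records (how the real 471 arose is
not documented; dropout removes observation records uniformly, never dose
events). The day-21 pre-dose sample is the model-predicted trough, since
the subject is near steady state; every pre-first-dose sample is 0 and
therefore BLQ. Records below the 50 ng/mL assay LLOQ are flagged BLQ and
excluded from estimation (the simplest defensible rule; the handling of
BLQ in the original analysis is not documented).

Covariates: laboratory values are independent truncated lognormals matched
to the cohort's median and IQR and truncated to its range; anthropometrics
are generated from sex (13:12 male:female), sex-specific height and BMI
distributions, and pushed through the derived-covariate formulas, so BMI,
BSA, LBW, IBW, BF%, CLcr are always internally consistent. The height/BMI
parameters were calibrated once against the cohort's LBW percentiles
(5th/95th targets 30.11/59.98 kg): the achievable 5th percentile is
bounded below by ≈29.2 kg given the published height/weight/BMI ranges
(the cohort's printed 5th percentile is effectively the minimum of 25
patients), and the calibrated generator attains ≈32.8/57.8, within 10% of
both targets, with all covariate medians inside the published IQRs.

What the generator does not emulate: covariate correlations beyond those
induced by the anthropometric construction (labs are drawn independently
unless a correlation matrix is supplied), assay drift, re-analysis,
enrollment dynamics, time-varying covariates, or inter-occasion
variability. Passing tests therefore demonstrate correctness of the
machinery under the assumed model, not robustness to real-data features
the model omits.

## Verification problem sizes

The statistical test suites run at sizes chosen to make their assertions
meaningful while keeping the suite practical: parameter recovery refits
five replicate trials at the full 25-subject design from NCA-informed
starts; NPDE null calibration uses 50 replicate trials with 500 simulation
replicates each; the forward-selection type-I experiment uses 20
replicates of a reduced 12-subject design with a covariate-free truth;
bootstrap coverage uses 30 resamples of a covariate-free model. The
full-scale defaults (1000/1000/1000/500) remain the package defaults.

## Known limitations

- FOCE-ELS as implemented in Phoenix NLME is proprietary; this package's
  FOCE-with-interaction is the standard published equivalent, so OFVs are
  comparable in behaviour (ΔOFV decisions, χ² calibration) but not
  bit-identical to any other tool's.
- Tlag and its IIV are weakly identified by the nominal sampling grid
  (earliest sample 1 h, lag 0.35 h); recovery of the lag parameters is
  accordingly variable even when CL/F and V/F recover well.
- BLQ records are excluded rather than treated by a likelihood-based
  method (M3); with the default design this affects mostly pre-dose
  samples.
- The dose-proportionality statistic is a correlation of means, which is
  insensitive to intercept bias; the log-log variant is reported alongside
  for that reason.
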