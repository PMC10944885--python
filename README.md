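# poppk

Population pharmacokinetics of oral ORIN1001 — a first-in-class IRE1-α
endoribonuclease inhibitor in clinical development for advanced solid
tumors — as a reusable, tested Python pipeline: structural model,
nonlinear mixed-effects estimation, stepwise covariate selection, model
diagnostics, non-compartmental analysis and steady-state exposure
simulation, together with a synthetic-trial generator that emulates the
phase-I study design (the patient-level data are confidential).

## Who this is for

Pharmacometricians and statistical programmers who want a transparent,
scriptable PopPK workflow for a two-compartment oral drug — either to
reproduce this analysis on simulated data, to reuse the components
(FOCE objective, VPC/NPDE, stepwise ΔOFV search, steady-state simulator)
on their own models, or to study the operating characteristics of the
workflow itself (selection type-I error, bootstrap coverage, NPDE
calibration).

## The model

Two-compartment disposition, first-order absorption with lag time Tlag,
first-order elimination; all parameters apparent (V/F, CL/F, ...).
Hierarchy:

- individual parameters: P_ij = TVP_i · exp(η_ij), η ~ N(0, ω²) on
  {V/F, CL/F, Ka, Tlag};
- covariate effects as powers of the median-normalised covariate, e.g.
  the final clearance model

      CL/F (L/h) = 1.07 · (TBIL / 10.30)^−0.46 · (LBW / 45.13)^1.11

  with TBIL total bilirubin (μmol/L) and LBW lean body weight (kg);
- proportional residual error, SD = 0.197 · prediction.

Estimation is FOCE with interaction (per-subject conditional η modes,
Laplace/Gauss-Newton correction); model comparison uses ΔOFV against χ²
thresholds (3.84 forward, 6.64 backward). Diagnostics: CWRES-based GOF,
dose-arm-stratified nonparametric bootstrap, VPC and NPDE from a common
simulation harness. Steady-state exposure (Cmin,ss, Cmax,ss, AUC_ss) is
evaluated in closed form and compared across covariate-percentile
scenarios under the 80–125% clinical-significance window.

See `docs/methods.md` for the full model account, numerical choices and
limitations.

## Worked example

```python
from poppk import final_model, generate_trial, PopPKModel
from poppk.simulate import Scenario, simulate_scenario, fold_changes

model = final_model()                      # published estimates
ds = generate_trial(seed=1)                # synthetic 25-subject trial
print(len(ds.subjects), ds.n_observations) # -> 25 471

fit = PopPKModel(ds, model).fit(compute_rse=False)
print(f"{fit.params['tv_cl']:.3f} {fit.params['tv_v']:.2f}")
# -> 1.058 26.37   (refit of the generating model: CL/F ~1.07, V/F ~26.21)

ref = simulate_scenario(model, Scenario("reference", {}, n=500), seed=1)
hi = simulate_scenario(model, Scenario("TBIL p95", {"TBIL": 22.24}, n=500),
                       seed=1)
table = fold_changes(ref, [hi], seed=1).table
print(table[["metric", "fold_change", "clinically_significant"]].to_string(index=False))
#  metric  fold_change  clinically_significant
# cmin_ss     1.581653                    True
# cmax_ss     1.317377                    True
#  auc_ss     1.424875                    True
```

The refit shows the estimation machinery recovering the typical clearance
and central volume it generated the data with. The scenario table says a
patient at the cohort's 95th-percentile bilirubin is predicted ~58%
higher steady-state trough at 900 mg once daily than the reference
patient — outside the 80–125% window, hence clinically significant, the
analysis' headline finding for TBIL.

The same operations are available from the shell:

```sh
poppk generate --seed 1 --out trial.csv
poppk fit --data trial.csv --model final --out fit.json
poppk vpc --data trial.csv --n 1000 --seed 1 --out vpc.csv
poppk simulate --dose 900 --n 500 --seed 1 --out folds.csv
```

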