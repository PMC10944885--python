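# Published final population-PK model for oral ORIN1001 (point estimates).
# Version 1: two-compartment, first-order absorption with lag, proportional
# residual error; covariate effects normalised at cohort medians.
version: 1
typical:
  ka: 0.58     # 1/h
  tlag: 0.35   # h
  v: 26.21     # L (V/F)
  v2: 26.60    # L (V2/F)
  cl: 1.07     # L/h (CL/F)
  cl2: 0.75    # L/h (CL2/F)
effects:
- {parameter: cl, covariate: TBIL, exponent: -0.46, reference: 10.30}  # umol/L
- {parameter: cl, covariate: LBW, exponent: 1.11, reference: 45.13}    # kg
- {parameter: v2, covariate: LDH, exponent: 0.99, reference: 214.0}    # IU/L
- {parameter: cl2, covariate: LBW, exponent: 2.21, reference: 45.13}   # kg
iiv:  # omega^2 (variance of eta)
  v: 0.049
  cl: 0.067
  ka: 0.534
  tlag: 0.438
sigma:
  kind: proportional
  prop_sd: 0.197
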