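"""Derived baseline covariates from demographics and serum creatinine.

One switchboard for the anthropometric/renal formulas used when assembling
the covariate table, so an alternative formula can be swapped in one place:

- BMI (kg/m^2): weight / height_m^2
- BSA (m^2): DuBois-DuBois, 0.007184 * weight^0.425 * height_cm^0.725
- LBW (kg): Janmahasatian,
    male   9270 * weight / (6680 + 216 * BMI)
    female 9270 * weight / (8780 + 244 * BMI)
- IBW (kg): Devine, 50 (male) / 45.5 (female) + 2.3 kg per inch over 5 ft
- BF% : Deurenberg, 1.20 * BMI + 0.23 * age - 10.8 * male - 5.4
- CLcr (mL/min): Cockcroft-Gault with creatinine in mg/dL
    (88.4 umol/L per mg/dL), x0.85 for females
- adjusted weight (kg): IBW + 0.4 * (weight - IBW), applied only when
  BMI > 25 kg/m^2 (otherwise actual weight)
- adjusted CLcr: Cockcroft-Gault evaluated at the adjusted weight
"""

from __future__ import annotations

__all__ = ["derive_covariates"]

_CM_PER_INCH = 2.54
_UMOL_PER_MG_DL = 88.4


def derive_covariates(
    sex: str,
    age: float,
    height_cm: float,
    weight_kg: float,
    creatinine_umol_l: float | None = None,
) -> dict:
    """Compute the derived covariate set from basic demographics.

    Parameters
    ----------
    sex : {"male", "female"}
    age : years
    height_cm : cm
    weight_kg : kg
    creatinine_umol_l : serum creatinine in umol/L; when omitted the renal
        covariates (CLcr, adjusted CLcr) are left out.

    Returns
    -------
    dict with keys BMI, BSA, LBW, IBW, BFP, ADJWT and, when creatinine is
    given, CLCR and ADJCLCR.
    """
    sex = sex.lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for name, value in (("age", age), ("height", height_cm), ("weight", weight_kg)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    male = sex == "male"

    height_m = height_cm / 100.0
    bmi = weight_kg / height_m**2
    bsa = 0.007184 * weight_kg**0.425 * height_cm**0.725
    if male:
        lbw = 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
        ibw = 50.0 + 2.3 * max(height_cm / _CM_PER_INCH - 60.0, 0.0)
    else:
        lbw = 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
        ibw = 45.5 + 2.3 * max(height_cm / _CM_PER_INCH - 60.0, 0.0)
    bfp = 1.20 * bmi + 0.23 * age - 10.8 * male - 5.4
    adjwt = ibw + 0.4 * (weight_kg - ibw) if bmi > 25.0 else weight_kg

    out = {
        "BMI": bmi,
        "BSA": bsa,
        "LBW": lbw,
        "IBW": ibw,
        "BFP": bfp,
        "ADJWT": adjwt,
    }
    if creatinine_umol_l is not None:
        if creatinine_umol_l <= 0:
            raise ValueError("creatinine must be > 0")
        cr_mg_dl = creatinine_umol_l / _UMOL_PER_MG_DL
        factor = 1.0 if male else 0.85
        clcr = (140.0 - age) * weight_kg * factor / (72.0 * cr_mg_dl)
        adjclcr = (140.0 - age) * adjwt * factor / (72.0 * cr_mg_dl)
        out["CLCR"] = clcr
        out["ADJCLCR"] = adjclcr
    return out
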