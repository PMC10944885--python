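"""Synthetic phase-I trial generator.

Emulates the dose-escalation design the analysis assumes: 25 patients in
seven once-daily arms (100-900 mg), a single dose at t=0 observed for 96 h,
then 21 daily doses from 96 h to 576 h with a day-21 profile over
576-600 h.  Covariates are drawn to match the published cohort summaries
(medians, IQRs and ranges); anthropometric covariates are derived from
generated sex/height/weight rather than drawn independently, so they always
honour their defining formulas.  Concentrations come from the structural
model under a truth :class:`~poppk.model.PopulationModel` with lognormal
IIV and proportional residual error; records below the 50 ng/mL assay LLOQ
are flagged BLQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import derive_covariates
from .data import (
    ConcentrationRecord,
    DatasetValidationError,
    DoseEvent,
    LLOQ_NG_ML,
    Subject,
    TrialDataset,
)
from .model import PopulationModel, individual_params
from .structural import concentration_at

__all__ = [
    "TrialDesign",
    "default_design",
    "generate_cohort_covariates",
    "generate_trial",
]


@dataclass
class TrialDesign:
    """Dosing schedule and nominal sampling times of the emulated study."""

    arms: dict = field(
        default_factory=lambda: {100: 3, 200: 3, 300: 4, 400: 3, 500: 3, 650: 5, 900: 4}
    )
    single_dose_times: tuple = (0, 1, 2, 4, 6, 8, 12, 24, 48, 72, 96)
    day21_offsets: tuple = (0, 1, 2, 4, 6, 8, 12, 24)
    first_daily_dose_h: float = 96.0
    last_daily_dose_h: float = 576.0
    tau_h: float = 24.0
    dropout: float = 4.0 / 475.0  # fraction of observation records removed

    @property
    def n_subjects(self) -> int:
        return sum(self.arms.values())

    def dose_times(self) -> np.ndarray:
        daily = np.arange(self.first_daily_dose_h, self.last_daily_dose_h + 1e-9,
                          self.tau_h)
        return np.concatenate([[0.0], daily])

    def sampling_times(self) -> np.ndarray:
        day21 = self.last_daily_dose_h + np.asarray(self.day21_offsets, dtype=float)
        return np.concatenate([np.asarray(self.single_dose_times, float), day21])


def default_design() -> TrialDesign:
    return TrialDesign()


# ---------------------------------------------------------------------------
# covariate distributions, calibrated to the published cohort summaries

# labs: lognormal (median, log-scale sigma from the IQR), truncated to the
# observed range
_LAB_DISTRIBUTIONS = {
    "TBIL": (10.30, 0.348, (4.80, 23.20)),  # umol/L
    "LDH": (214.0, 0.323, (98.0, 1268.0)),  # IU/L
    "BUN": (8.94, 0.328, (3.70, 16.28)),  # mmol/L
    "CR": (58.0, 0.243, (31.0, 89.0)),  # umol/L
    "ALT": (18.7, 0.642, (3.0, 37.0)),  # IU/L
    "AST": (22.0, 0.405, (10.0, 77.0)),  # IU/L
    "ALP": (85.0, 0.692, (31.0, 304.0)),  # IU/L
}

# anthropometrics: sex-specific height (normal) and BMI (lognormal), both
# truncated; weight = BMI * height^2 with the cohort weight range enforced.
# Calibrated once so the derived LBW distribution reproduces the cohort's
# 5th/95th percentiles (30.11 / 59.98 kg) and range.
_HEIGHT = {"male": (171.0, 5.0, (160.0, 178.0)), "female": (156.0, 5.5, (150.0, 171.0))}
_BMI = {"male": (23.2, 0.17, (18.67, 28.72)), "female": (23.3, 0.19, (18.67, 28.72))}
_WEIGHT_RANGE = (42.0, 80.0)
_AGE = (57.0, 10.0, (37.0, 72.0))
_MALE_FRACTION = 13 / 25


def _truncated(rng, sampler, lo, hi, size):
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = sampler(rng, need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _trunc_lognormal(rng, median, sigma, lo, hi, size):
    return _truncated(
        rng, lambda r, n: np.exp(r.normal(np.log(median), sigma, n)), lo, hi, size
    )


def _trunc_normal(rng, mu, sd, lo, hi, size):
    return _truncated(rng, lambda r, n: r.normal(mu, sd, n), lo, hi, size)


def generate_cohort_covariates(n: int, seed: int, male_fraction: float = _MALE_FRACTION
                               ) -> list[Subject]:
    """Draw ``n`` internally consistent covariate sets (no dose assignment).

    Returned subjects have dose_mg=1 placeholder; :func:`generate_trial`
    assigns arms.  Derived covariates (BMI, BSA, LBW, IBW, BF%, CLcr, ...)
    are computed from the generated demographics, never drawn independently.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < male_fraction, "male", "female")
    subjects = []
    age = _trunc_normal(rng, *_AGE[:2], *_AGE[2], size=n)
    labs = {
        name: _trunc_lognormal(rng, med, sig, lo, hi, n)
        for name, (med, sig, (lo, hi)) in _LAB_DISTRIBUTIONS.items()
    }
    for i in range(n):
        s = sex[i]
        while True:
            ht = _trunc_normal(rng, *_HEIGHT[s][:2], *_HEIGHT[s][2], size=1)[0]
            bmi = _trunc_lognormal(rng, *_BMI[s][:2], *_BMI[s][2], size=1)[0]
            wt = bmi * (ht / 100.0) ** 2
            if _WEIGHT_RANGE[0] <= wt <= _WEIGHT_RANGE[1]:
                break
        derived = derive_covariates(
            sex=s, age=age[i], height_cm=ht, weight_kg=wt,
            creatinine_umol_l=labs["CR"][i],
        )
        cov = {
            "SEX": 1.0 if s == "male" else 0.0,
            "AGE": age[i],
            "HT": ht,
            "WT": wt,
            **{k: labs[k][i] for k in labs},
            **derived,
        }
        subjects.append(
            Subject(id=f"S{i + 1:03d}", dose_mg=1.0,
                    covariates={k: float(v) for k, v in cov.items()})
        )
    return subjects


def generate_trial(
    design: TrialDesign | None = None,
    truth: PopulationModel | None = None,
    seed: int = 0,
) -> TrialDataset:
    """Simulate one complete trial dataset from a truth model.

    Concentrations are the structural predictions at each subject's
    individual parameters (eta ~ N(0, omega^2)) perturbed by proportional
    residual error and truncated at zero; samples below the assay LLOQ
    (50 ng/mL, including every pre-first-dose sample) are flagged BLQ.
    The day-21 pre-dose sample at 576 h is the model-predicted trough: the
    576 h dose has not begun absorbing at its own nominal time.
    """
    from .model import final_model

    design = design or default_design()
    truth = truth or final_model()
    if not (0.0 <= design.dropout < 0.5):
        raise DatasetValidationError("dropout fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    cov_seed = int(rng.integers(2**31 - 1))
    subjects = generate_cohort_covariates(design.n_subjects, seed=cov_seed)

    # assign dose arms in enrollment order
    dose_per_subject = np.concatenate(
        [np.full(n_arm, dose) for dose, n_arm in design.arms.items()]
    )
    subjects = [
        Subject(id=s.id, dose_mg=float(d), covariates=s.covariates)
        for s, d in zip(subjects, dose_per_subject)
    ]

    omega = truth.omega_matrix()
    chol = np.linalg.cholesky(omega) if len(truth.eta_params) else None
    times = design.sampling_times()
    dose_times = design.dose_times()

    doses, observations = [], []
    for s in subjects:
        for t in dose_times:
            doses.append(DoseEvent(subject_id=s.id, time=float(t), amount=s.dose_mg))
        if chol is not None:
            eta = chol @ rng.standard_normal(len(truth.eta_params))
        else:
            eta = np.zeros(0)
        p = individual_params(truth, s, eta)
        f = concentration_at(p, [(t, s.dose_mg) for t in dose_times], times)
        eps = rng.standard_normal(len(times))
        y = np.maximum(f * (1.0 + truth.sigma.prop_sd * eps), 0.0)
        if truth.sigma.kind in ("additive", "combined"):
            y = np.maximum(y + truth.sigma.add_sd * rng.standard_normal(len(times)), 0.0)
        for t, dv in zip(times, y):
            observations.append(
                ConcentrationRecord(
                    subject_id=s.id, time=float(t), dv=float(dv),
                    is_blq=bool(dv < LLOQ_NG_ML),
                )
            )

    n_drop = int(round(design.dropout * len(observations)))
    if n_drop:
        drop_idx = set(rng.choice(len(observations), size=n_drop, replace=False))
        observations = [r for i, r in enumerate(observations) if i not in drop_idx]

    return TrialDataset(
        subjects=subjects,
        doses=doses,
        observations=observations,
        meta={"seed": seed, "generator": "poppk.trial", "design": "default"},
    )
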