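"""Two-compartment disposition with first-order absorption and lag time.

Concentrations are evaluated in closed form.  For a single oral dose ``D``
(mg) given at time ``t_d``, absorption starts after the lag ``Tlag`` and the
central-compartment concentration at ``t' = t - t_d - Tlag > 0`` is the
standard tri-exponential

    C(t') = 1000 * D * ka / V * [ A e^{-alpha t'} + B e^{-beta t'}
                                  + C e^{-ka t'} ]

with macro constants ``alpha, beta`` derived from the micro constants
``k10 = CL/V``, ``k12 = CL2/V``, ``k21 = CL2/V2`` and coefficients

    A = (k21 - alpha) / ((ka - alpha)(beta - alpha))
    B = (k21 - beta)  / ((ka - beta)(alpha - beta))
    C = (k21 - ka)    / ((alpha - ka)(beta - ka)).

The factor 1000 converts mg/L to ng/mL.  Multiple doses superpose linearly;
steady state under a fixed interval follows from summing the geometric
series of each exponential term.  All parameters are apparent (bioavailability
F is absorbed into V/F, CL/F, ...), so F never appears explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import DoseEvent

__all__ = [
    "PKParameters",
    "ConcentrationProfile",
    "ExposureMetrics",
    "disposition_constants",
    "predict_concentration",
    "concentration_at",
    "steady_state_profile",
    "steady_state_metrics",
]

# Relative separation below which Ka is nudged off a disposition constant to
# avoid the removable singularity of the closed form.
_DEGENERACY_TOL = 1e-10
_DEGENERACY_NUDGE = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Individual structural parameters (all apparent, i.e. scaled by 1/F).

    Attributes
    ----------
    ka : float
        First-order absorption rate constant (1/h).
    tlag : float
        Absorption lag time (h).
    v : float
        Central volume of distribution V/F (L).
    v2 : float
        Peripheral volume V2/F (L).
    cl : float
        Elimination clearance CL/F (L/h).
    cl2 : float
        Inter-compartmental clearance CL2/F (L/h).
    """

    ka: float
    tlag: float
    v: float
    v2: float
    cl: float
    cl2: float

    def __post_init__(self) -> None:
        for name in ("ka", "v", "v2", "cl", "cl2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be > 0")
        if self.tlag < 0:
            raise ValueError("tlag must be >= 0")


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray
    concentrations: np.ndarray


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure over one dosing interval."""

    cmin_ss: float  # trough, ng/mL (concentration tau h after a dose)
    cmax_ss: float  # peak, ng/mL
    auc_ss: float  # ng*h/mL over one interval


def disposition_constants(p: PKParameters) -> dict:
    """Micro and macro rate constants of the two-compartment disposition."""
    k10 = p.cl / p.v
    k12 = p.cl2 / p.v
    k21 = p.cl2 / p.v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return {"k10": k10, "k12": k12, "k21": k21, "alpha": alpha, "beta": beta}


def _exponential_terms(p: PKParameters):
    """Rates (alpha, beta, ka) and matched coefficients for a unit dose.

    Coefficients are in ng/mL per mg of dose; Ka is perturbed slightly when
    numerically coincident with a disposition constant (removable
    singularity of the closed form).
    """
    d = disposition_constants(p)
    alpha, beta, k21 = d["alpha"], d["beta"], d["k21"]
    ka = p.ka
    for lam in (alpha, beta):
        if abs(ka - lam) <= _DEGENERACY_TOL * max(ka, lam):
            ka = ka * (1.0 + _DEGENERACY_NUDGE)
    scale = 1000.0 * ka / p.v  # mg -> ng/mL
    rates = np.array([alpha, beta, ka])
    coefs = scale * np.array(
        [
            (k21 - alpha) / ((ka - alpha) * (beta - alpha)),
            (k21 - beta) / ((ka - beta) * (alpha - beta)),
            (k21 - ka) / ((alpha - ka) * (beta - ka)),
        ]
    )
    return rates, coefs


def predict_concentration(
    p: PKParameters,
    doses: Sequence[DoseEvent] | Iterable,
    times: Sequence[float],
) -> ConcentrationProfile:
    """Concentration-time profile for an arbitrary oral dosing history.

    ``doses`` may be :class:`~poppk.data.DoseEvent` objects or ``(time,
    amount)`` pairs, sorted by time.  Superposition of the closed-form
    single-dose solution; contributions are zero until ``tlag`` after each
    dose.
    """
    times = np.asarray(times, dtype=float)
    dose_times, amounts = _dose_arrays(doses)
    conc = _superpose(p, dose_times, amounts, times)
    return ConcentrationProfile(times=times, concentrations=conc)


def concentration_at(p: PKParameters, doses, times) -> np.ndarray:
    """Bare ndarray version of :func:`predict_concentration`."""
    times = np.asarray(times, dtype=float)
    dose_times, amounts = _dose_arrays(doses)
    return _superpose(p, dose_times, amounts, times)


def _dose_arrays(doses):
    dose_times, amounts = [], []
    for ev in doses:
        if isinstance(ev, DoseEvent):
            dose_times.append(ev.time)
            amounts.append(ev.amount)
        else:
            t, a = ev
            dose_times.append(float(t))
            amounts.append(float(a))
    return np.asarray(dose_times), np.asarray(amounts)


def _superpose(p, dose_times, amounts, times):
    rates, coefs = _exponential_terms(p)
    # dt[i, j] = time since absorption onset of dose j at observation i
    dt = times[:, None] - dose_times[None, :] - p.tlag
    active = dt > 0
    dt = np.where(active, dt, 0.0)
    # (n_times, n_doses, 3) exponentials collapsed over terms then doses
    e = np.exp(-dt[:, :, None] * rates[None, None, :])
    per_dose = e @ coefs
    conc = np.sum(np.where(active, per_dose, 0.0) * amounts[None, :], axis=1)
    return np.maximum(conc, 0.0)


def concentration_batch(theta: np.ndarray, dose_times, amounts, times) -> np.ndarray:
    """Concentrations for many parameter sets sharing one dosing history.

    ``theta`` has shape (m, 6) with columns ordered (ka, tlag, v, v2, cl,
    cl2); returns an (m, n_times) array.  Used by the estimation inner loop
    (value + finite-difference Jacobian in one call) and by the Monte Carlo
    simulation harness.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    dose_times = np.asarray(dose_times, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _concentration_batch_impl(theta, dose_times, amounts, times)


def _concentration_batch_impl(theta, dose_times, amounts, times):
    ka, tlag, v, v2, cl, cl2 = theta.T
    k10 = cl / v
    k12 = cl2 / v
    k21 = cl2 / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    near = np.minimum(np.abs(ka - alpha), np.abs(ka - beta)) <= (
        _DEGENERACY_TOL * np.maximum(ka, alpha)
    )
    ka = np.where(near, ka * (1.0 + _DEGENERACY_NUDGE), ka)
    scale = 1000.0 * ka / v
    coefs = scale[:, None] * np.stack(
        [
            (k21 - alpha) / ((ka - alpha) * (beta - alpha)),
            (k21 - beta) / ((ka - beta) * (alpha - beta)),
            (k21 - ka) / ((alpha - ka) * (beta - ka)),
        ],
        axis=1,
    )  # (m, 3)
    rates = np.stack([alpha, beta, ka], axis=1)  # (m, 3)
    # (m, T, D)
    dt = times[None, :, None] - dose_times[None, None, :] - tlag[:, None, None]
    active = dt > 0
    dt = np.where(active, dt, 0.0)
    e = np.exp(-dt[:, :, :, None] * rates[:, None, None, :])  # (m, T, D, 3)
    per_dose = np.einsum("mtdk,mk->mtd", e, coefs)
    conc = np.sum(np.where(active, per_dose, 0.0) * amounts[None, None, :], axis=2)
    return np.maximum(conc, 0.0)


def steady_state_profile(
    p: PKParameters, dose: float, tau: float, times: Sequence[float]
) -> np.ndarray:
    """Steady-state concentration at ``times`` (h) after a dose, interval tau.

    Each exponential term accumulates by its geometric series
    ``e^{-lam u} / (1 - e^{-lam tau})`` where ``u = (t - tlag) mod tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dose <= 0:
        raise ValueError("dose must be > 0")
    times = np.asarray(times, dtype=float)
    rates, coefs = _exponential_terms(p)
    u = np.mod(times - p.tlag, tau)
    accum = np.exp(-u[:, None] * rates[None, :]) / (1.0 - np.exp(-rates * tau))
    return np.maximum(dose * (accum @ coefs), 0.0)


def steady_state_metrics(
    p: PKParameters, dose: float, tau: float, grid_step: float = 0.05
) -> ExposureMetrics:
    """Trough, peak and AUC over one dosing interval at steady state.

    The trough is the concentration ``tau`` h after a dose (immediately
    before the next one).  The peak is located on a ``grid_step`` grid over
    one interval and refined by golden-section search; the AUC over one
    interval is exactly ``dose / CL`` for this linear model and is computed
    that way (in ng*h/mL).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dose <= 0:
        raise ValueError("dose must be > 0")
    cmin = float(steady_state_profile(p, dose, tau, [tau])[0])

    grid = np.arange(0.0, tau + grid_step, grid_step)
    grid = grid[grid <= tau]
    conc = steady_state_profile(p, dose, tau, grid)
    i = int(np.argmax(conc))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    cmax = _golden_max(
        lambda t: float(steady_state_profile(p, dose, tau, [t])[0]), lo, hi
    )
    cmax = max(cmax, float(conc[i]))

    auc = 1000.0 * dose / p.cl  # mg/(L/h) = mg*h/L = 1000 ng*h/mL
    return ExposureMetrics(cmin_ss=cmin, cmax_ss=cmax, auc_ss=auc)


def _golden_max(f, lo, hi, tol=1e-6):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return max(fc, fd)
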