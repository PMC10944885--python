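"""Non-compartmental analysis and dose-proportionality assessment.

NCA metrics per individual profile: Cmax/Tmax read off the observed points,
AUC by the linear-up/log-down trapezoid, the terminal slope lambda_z by
log-linear regression over the best adjusted-r^2 tail (3 to 6 points,
excluding Tmax), and the derived t1/2 = ln2/lambda_z, CL/F = dose/AUC0-inf,
Vz/F = CL/F / lambda_z.

Dose proportionality: Pearson correlation R of per-arm mean exposure
against dose (with a log-log variant), reported to two decimals; linearity
is conventionally declared at R >= 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["NcaResult", "DoseProportionality", "nca_profile", "dose_proportionality"]


@dataclass(frozen=True)
class NcaResult:
    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float | None  # ng*h/mL; None when no credible terminal phase
    lambda_z: float | None  # 1/h
    t_half: float | None  # h
    cl_f: float | None  # L/h
    vz_f: float | None  # L
    lambda_z_r2: float | None = None
    lambda_z_n_points: int | None = None


@dataclass(frozen=True)
class DoseProportionality:
    metric: str
    doses: tuple
    mean_exposures: tuple
    r: float  # Pearson R of mean exposure vs dose, 2 decimals
    r_loglog: float  # Pearson R of log mean exposure vs log dose


def _auc_linear_up_log_down(t, c):
    """Trapezoid AUC: linear when rising, log when falling between positives."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def _terminal_slope(t, c, tmax_idx):
    """Best adjusted-r^2 log-linear fit over the last 3..6 points after Tmax."""
    candidates = [
        i for i in range(len(t)) if i > tmax_idx and c[i] > 0
    ]
    best = None
    for k in range(3, 7):
        if len(candidates) < k:
            break
        idx = candidates[-k:]
        x, y = t[idx], np.log(c[idx])
        slope, intercept, r, _, _ = stats.linregress(x, y)
        if slope >= 0:
            continue
        r2 = r * r
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[0]:
            best = (adj, -slope, r2, k)
    return best  # (adj_r2, lambda_z, r2, n_points) or None


def nca_profile(times, concentrations, dose_mg: float) -> NcaResult:
    """NCA for a single-dose concentration-time profile.

    Requires at least 3 positive concentrations.  When the terminal phase
    is not credible (fewer than 3 usable tail points or r^2 < 0.8) the
    extrapolated metrics (AUC0-inf, lambda_z, t1/2, CL/F, Vz/F) are None.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be 1-D and equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.sum(c > 0) < 3:
        raise ValueError("need at least 3 positive concentrations")
    if dose_mg <= 0:
        raise ValueError("dose must be > 0")

    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_t = float(_auc_linear_up_log_down(t, c))

    fit = _terminal_slope(t, c, i_max)
    if fit is None or fit[2] < 0.8:
        return NcaResult(cmax, tmax, auc_t, None, None, None, None, None)
    _, lam, r2, npts = fit
    c_last = float(c[c > 0][-1])
    auc_inf = auc_t + c_last / lam
    cl_f = 1000.0 * dose_mg / auc_inf  # mg / (ng*h/mL) -> L/h
    return NcaResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=lam,
        t_half=float(np.log(2.0) / lam),
        cl_f=cl_f,
        vz_f=cl_f / lam,
        lambda_z_r2=r2,
        lambda_z_n_points=npts,
    )


def dose_proportionality(mean_exposures, doses, metric: str = "exposure"
                         ) -> DoseProportionality:
    """Linearity of mean exposure across dose arms.

    ``r`` is the plain Pearson correlation of per-dose means against dose,
    rounded to 2 decimals as conventionally reported; ``r_loglog`` is the
    Pearson correlation on the log-log scale.
    """
    y = np.asarray(mean_exposures, dtype=float)
    x = np.asarray(doses, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 dose levels")
    if len(x) != len(y):
        raise ValueError("doses and mean exposures must align")
    r = float(stats.pearsonr(x, y)[0])
    r_ll = float(stats.pearsonr(np.log(x), np.log(y))[0])
    return DoseProportionality(
        metric=metric,
        doses=tuple(x),
        mean_exposures=tuple(y),
        r=round(r, 2),
        r_loglog=round(r_ll, 2),
    )
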