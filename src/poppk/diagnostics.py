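"""Model validation: GOF quantities, non-parametric bootstrap, VPC, NPDE.

VPC and NPDE consume the same Monte Carlo harness
(:func:`simulate_observations`): replicate datasets are simulated at the
observed design — each subject keeps their doses, sampling times and
covariates, with fresh eta and residual draws per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Subject, TrialDataset
from .estimation import (
    PopPKModel,
    PopPKResults,
    _prepare_subjects,
    _subject_base_params,
    _variance,
)
from .model import PopulationModel
from .structural import concentration_batch

__all__ = [
    "gof",
    "bootstrap",
    "vpc",
    "npde",
    "simulate_observations",
    "GofTable",
    "BootstrapResult",
    "VpcResult",
    "NpdeResult",
]

_PCTL = (5.0, 50.0, 95.0)


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class GofTable:
    table: pd.DataFrame  # per-observation DV/PRED/IPRED/CWRES/time/TAD

    def plot(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.table
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        for ax, x, y in (
            (axes[0, 0], "PRED", "DV"),
            (axes[0, 1], "IPRED", "DV"),
            (axes[1, 0], "PRED", "CWRES"),
            (axes[1, 1], "TIME", "CWRES"),
        ):
            ax.scatter(t[x], t[y], s=12, alpha=0.6)
            if y == "DV":
                lim = [0, max(t[x].max(), t[y].max())]
                ax.plot(lim, lim, "k-", lw=1)
            else:
                ax.axhline(0, color="k", lw=1)
            ax.set_xlabel(x)
            ax.set_ylabel(y)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def gof(fit: PopPKResults) -> GofTable:
    """DV, PRED, IPRED, CWRES per non-BLQ observation.

    CWRES follows the FOCE linearisation: per subject, the model-implied
    covariance ``V = J Omega J' + R(eta*)`` at the conditional mode
    decorrelates the linearised residual ``y - f(eta*) + J eta*``.
    """
    spec = fit.spec
    ds = fit.model.dataset
    from .estimation import _PARAM_INDEX

    subjects = _prepare_subjects(ds)
    eta_idx = np.array([_PARAM_INDEX[p] for p in spec.eta_params], dtype=int)
    omega = spec.omega_matrix()
    rows = []
    for sd in subjects:
        if len(sd.y) == 0:
            continue
        eta = np.asarray(fit.etas.get(sd.sid, np.zeros(len(spec.eta_params))))
        base = _subject_base_params(spec, sd.subject)

        def conc_for(etas):
            theta = np.tile(base, (len(etas), 1))
            if len(eta_idx):
                theta[:, eta_idx] *= np.exp(etas)
            return concentration_batch(theta, sd.dose_times, sd.amounts, sd.times)

        pred = conc_for(np.zeros((1, len(eta_idx))))[0]
        ipred = conc_for(eta[None, :])[0]
        v = _variance(ipred, spec.sigma)
        if len(eta_idx):
            h = 1e-5
            pts = eta[None, :] + h * np.eye(len(eta_idx))
            fp = conc_for(pts)
            J = (fp - ipred[None, :]).T / h
            V = J @ omega @ J.T + np.diag(v)
            resid = sd.y - ipred + J @ eta
            L = np.linalg.cholesky(V)
            cwres = np.linalg.solve(L, resid)
        else:
            cwres = (sd.y - pred) / np.sqrt(v)
        tad = np.array(
            [
                t - sd.dose_times[sd.dose_times < t].max()
                if np.any(sd.dose_times < t)
                else t
                for t in sd.times
            ]
        )
        for i in range(len(sd.y)):
            rows.append(
                {
                    "ID": sd.sid,
                    "TIME": sd.times[i],
                    "TAD": tad[i],
                    "DV": sd.y[i],
                    "PRED": pred[i],
                    "IPRED": ipred[i],
                    "CWRES": cwres[i],
                }
            )
    return GofTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    summary: pd.DataFrame  # per parameter: median, rse%, ci_lo, ci_hi
    n_success: int
    n_requested: int
    stratified: bool
    seed: int
    samples: pd.DataFrame | None = None


def bootstrap(
    fit: PopPKResults,
    n: int = 1000,
    seed: int = 0,
    stratify: bool = True,
    keep_samples: bool = False,
    **fit_kw,
) -> BootstrapResult:
    """Non-parametric bootstrap: resample subjects, refit, percentile CIs.

    Resampling is with replacement and, by default, stratified by dose arm
    so every resampled trial spans the dose range (arm sizes of 2-5 make
    unstratified resamples degenerate).  Failed refits are logged in
    ``n_success`` and excluded from the percentiles.
    """
    ds = fit.model.dataset
    rng = np.random.default_rng(seed)
    arms: dict[float, list[Subject]] = {}
    for s in ds.subjects:
        arms.setdefault(s.dose_mg, []).append(s)
    rows = []
    n_success = 0
    for _ in range(n):
        if stratify:
            chosen = [
                arm[i]
                for arm in arms.values()
                for i in rng.integers(0, len(arm), size=len(arm))
            ]
        else:
            all_subj = ds.subjects
            chosen = [all_subj[i] for i in rng.integers(0, len(all_subj), len(all_subj))]
        resampled = _clone_dataset(ds, chosen)
        try:
            res = PopPKModel(
                resampled, fit.spec,
                fix_typical=fit.model.packing.fix_typical,
            ).fit(compute_rse=False, **fit_kw)
            rows.append(res.params)
            n_success += 1
        except (ValueError, np.linalg.LinAlgError):
            continue
    samples = pd.DataFrame(rows)
    med = samples.median()
    sd = samples.std(ddof=1)
    summary = pd.DataFrame(
        {
            "median": med,
            "rse_percent": 100.0 * sd / med.abs(),
            "ci_lo": samples.quantile(0.025),
            "ci_hi": samples.quantile(0.975),
        }
    )
    return BootstrapResult(
        summary=summary,
        n_success=n_success,
        n_requested=n,
        stratified=stratify,
        seed=seed,
        samples=samples if keep_samples else None,
    )


def _clone_dataset(ds: TrialDataset, chosen) -> TrialDataset:
    from .data import ConcentrationRecord, DoseEvent

    subjects, doses, obs = [], [], []
    for k, s in enumerate(chosen):
        new_id = f"B{k + 1:03d}"
        subjects.append(Subject(id=new_id, dose_mg=s.dose_mg, covariates=s.covariates))
        for d in ds.doses_for(s.id):
            doses.append(DoseEvent(subject_id=new_id, time=d.time, amount=d.amount))
        for r in ds.observations:
            if r.subject_id == s.id:
                obs.append(
                    ConcentrationRecord(
                        subject_id=new_id, time=r.time, dv=r.dv, is_blq=r.is_blq
                    )
                )
    return TrialDataset(subjects, doses, obs, meta=dict(ds.meta))


# ---------------------------------------------------------------------------
# simulation harness (shared by VPC and NPDE)


def simulate_observations(
    spec: PopulationModel, ds: TrialDataset, n: int, rng
) -> dict:
    """Simulate ``n`` replicates of every subject's observation vector.

    Returns sid -> (n, n_i) array of simulated concentrations at the
    subject's non-BLQ observation times, with fresh eta and proportional
    (and/or additive) residual noise per replicate; negative draws truncate
    at zero.
    """
    from .estimation import _PARAM_INDEX

    subjects = _prepare_subjects(ds)
    q = len(spec.eta_params)
    eta_idx = np.array([_PARAM_INDEX[p] for p in spec.eta_params], dtype=int)
    chol = np.linalg.cholesky(spec.omega_matrix()) if q else None
    out = {}
    for sd in subjects:
        if len(sd.y) == 0:
            out[sd.sid] = np.zeros((n, 0))
            continue
        base = _subject_base_params(spec, sd.subject)
        theta = np.tile(base, (n, 1))
        if q:
            etas = rng.standard_normal((n, q)) @ chol.T
            theta[:, eta_idx] *= np.exp(etas)
        f = concentration_batch(theta, sd.dose_times, sd.amounts, sd.times)
        y = f.copy()
        if spec.sigma.kind in ("proportional", "combined"):
            y = f * (1.0 + spec.sigma.prop_sd * rng.standard_normal(f.shape))
        if spec.sigma.kind in ("additive", "combined"):
            y = y + spec.sigma.add_sd * rng.standard_normal(f.shape)
        out[sd.sid] = np.maximum(y, 0.0)
    return out


# ---------------------------------------------------------------------------
# VPC


@dataclass
class VpcResult:
    table: pd.DataFrame  # per bin: observed percentiles + simulated CIs
    by: str  # "time" or "tad"
    n_replicates: int
    seed: int

    def plot(self, path=None, log_y: bool = True):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.table
        fig, ax = plt.subplots(figsize=(8, 5))
        for p, color in zip(_PCTL, ("tab:blue", "tab:red", "tab:blue")):
            key = f"p{p:g}"
            ax.plot(t["bin"], t[f"obs_{key}"], "o-", color=color, ms=4,
                    label=f"observed {p:g}th")
            ax.fill_between(
                t["bin"], t[f"sim_{key}_lo"], t[f"sim_{key}_hi"],
                alpha=0.25, color=color,
            )
        if log_y:
            ax.set_yscale("log")
        ax.set_xlabel("time after dose (h)" if self.by == "tad" else "time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def vpc(
    spec: PopulationModel,
    ds: TrialDataset,
    n: int = 1000,
    seed: int = 0,
    bins=None,
    by: str = "time",
    time_window=None,
) -> VpcResult:
    """Visual predictive check at the observed design.

    Observations are binned on the nominal sampling times (the design is
    nominal-time sparse sampling), or on time-after-dose with ``by="tad"``.
    Per bin the 5th/50th/95th observed percentiles are compared with the
    95% CI of the same percentiles across ``n`` simulated replicates.
    ``time_window=(lo, hi)`` restricts to a time range, e.g. (0, 96) or
    (576, 600).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sims = simulate_observations(spec, ds, n, rng)
    subjects = _prepare_subjects(ds)

    times, dvs, sim_cols = [], [], []
    for sd in subjects:
        if len(sd.y) == 0:
            continue
        if by == "tad":
            axis = np.array(
                [
                    t - sd.dose_times[sd.dose_times < t].max()
                    if np.any(sd.dose_times < t)
                    else t
                    for t in sd.times
                ]
            )
        else:
            axis = sd.times
        times.append(axis)
        dvs.append(sd.y)
        sim_cols.append(sims[sd.sid])
    times = np.concatenate(times)
    dvs = np.concatenate(dvs)
    sim_all = np.concatenate(sim_cols, axis=1)  # (n, total_obs)

    if time_window is not None:
        keep = (times >= time_window[0]) & (times <= time_window[1])
        times, dvs, sim_all = times[keep], dvs[keep], sim_all[:, keep]

    bin_values = np.unique(times) if bins is None else np.asarray(bins, float)
    if bins is None:
        assign = times
    else:  # nearest bin centre
        assign = bin_values[np.argmin(np.abs(times[:, None] - bin_values[None, :]), axis=1)]

    rows = []
    for b in bin_values:
        mask = assign == b
        if not mask.any():
            continue
        row = {"bin": b, "n_obs": int(mask.sum())}
        obs_p = np.percentile(dvs[mask], _PCTL)
        sim_p = np.percentile(sim_all[:, mask], _PCTL, axis=1)  # (3, n)
        ci = np.percentile(sim_p, [2.5, 97.5], axis=1)  # (2, 3)
        for j, p in enumerate(_PCTL):
            key = f"p{p:g}"
            row[f"obs_{key}"] = obs_p[j]
            row[f"sim_{key}_lo"] = ci[0, j]
            row[f"sim_{key}_hi"] = ci[1, j]
        rows.append(row)
    return VpcResult(
        table=pd.DataFrame(rows), by=by, n_replicates=n, seed=seed
    )


# ---------------------------------------------------------------------------
# NPDE


@dataclass
class NpdeResult:
    table: pd.DataFrame  # per observation: ID, TIME, DV, NPDE
    t_test_p: float  # H0: mean 0
    variance_test_p: float  # H0: variance 1 (chi-square on (n-1) s^2)
    shapiro_p: float  # H0: normal
    n_replicates: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.table["NPDE"].mean())

    @property
    def variance(self) -> float:
        return float(self.table["NPDE"].var(ddof=1))


def npde(
    spec: PopulationModel, ds: TrialDataset, n: int = 1000, seed: int = 0
) -> NpdeResult:
    """Normalised prediction distribution errors with summary tests.

    Per subject the simulated ensemble's mean and covariance decorrelate
    both the observed vector and every simulated vector (Cholesky); the
    rank of each decorrelated observation within its simulated ensemble,
    clipped to [1/(2n), 1 - 1/(2n)], maps through the standard-normal
    quantile function.  Under a correct model the NPDE are iid N(0, 1).
    """
    if n < 2:
        raise ValueError("NPDE needs at least 2 simulation replicates")
    rng = np.random.default_rng(seed)
    sims = simulate_observations(spec, ds, n, rng)
    subjects = _prepare_subjects(ds)
    rows = []
    for sd in subjects:
        n_i = len(sd.y)
        if n_i == 0:
            continue
        S = sims[sd.sid]  # (n, n_i)
        m = S.mean(axis=0)
        C = np.cov(S, rowvar=False).reshape(n_i, n_i)
        # guard against a numerically singular ensemble covariance
        C += 1e-10 * np.eye(n_i) * max(np.trace(C) / n_i, 1.0)
        L = np.linalg.cholesky(C)
        y_star = np.linalg.solve(L, sd.y - m)
        s_star = np.linalg.solve(L, (S - m).T)  # (n_i, n)
        pd_i = (s_star < y_star[:, None]).mean(axis=1)
        pd_i = np.clip(pd_i, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        npde_i = stats.norm.ppf(pd_i)
        for t, dv, val in zip(sd.times, sd.y, npde_i):
            rows.append({"ID": sd.sid, "TIME": t, "DV": dv, "NPDE": val})
    table = pd.DataFrame(rows)
    x = table["NPDE"].to_numpy()
    t_p = float(stats.ttest_1samp(x, 0.0).pvalue)
    k = len(x) - 1
    chi2 = k * x.var(ddof=1)
    var_p = float(2 * min(stats.chi2.cdf(chi2, k), stats.chi2.sf(chi2, k)))
    sw_p = float(stats.shapiro(x).pvalue) if len(x) >= 3 else float("nan")
    return NpdeResult(
        table=table,
        t_test_p=t_p,
        variance_test_p=var_p,
        shapiro_p=sw_p,
        n_replicates=n,
        seed=seed,
    )
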