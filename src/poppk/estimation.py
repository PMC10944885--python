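"""FOCE estimation of the population model (statsmodels-style API).

:class:`PopPKModel` pairs a :class:`~poppk.data.TrialDataset` with a
:class:`~poppk.model.PopulationModel` specification; ``fit()`` returns a
:class:`PopPKResults` carrying estimates, their relative standard errors,
OFV/AIC/BIC, empirical-Bayes etas and a ``summary()`` table.  Diagnostics
(GOF, bootstrap, VPC, NPDE) hang off the results object.

The objective is -2x the FOCE-with-interaction approximation of the
marginal log-likelihood: per subject, the random effects eta are set to
their conditional mode (inner Newton iterations on the penalised
least-squares criterion, residual variance evaluated at the conditional
prediction), and the Laplace correction uses the Gauss-Newton Hessian

    OFV_j = g(eta*) + n_j ln(2 pi) + ln|Omega| + ln|J' V^-1 J + Omega^-1|

with ``g(eta) = sum_i [r_i^2 / v_i + ln v_i] + eta' Omega^-1 eta``.  The
outer search runs on log-transformed typical values and variance
components (covariate exponents unconstrained), so positivity needs no
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data import TrialDataset
from .model import (
    STRUCTURAL_PARAMS,
    CovariateEffect,
    PopulationModel,
    ResidualModel,
)
from .structural import concentration_batch

__all__ = [
    "PopPKModel",
    "PopPKResults",
    "ComparisonResult",
    "compare",
    "objective",
    "nca_informed_start",
]

# Predictions are floored at this value (ng/mL) inside the residual-variance
# computation so a proportional error model cannot produce zero variance.
_PRED_FLOOR = 0.5

_PARAM_INDEX = {name: i for i, name in enumerate(STRUCTURAL_PARAMS)}


@dataclass
class _SubjectData:
    """Per-subject arrays used by the likelihood inner loop."""

    sid: str
    subject: object
    times: np.ndarray  # non-BLQ observation times (h)
    y: np.ndarray  # observed concentrations (ng/mL)
    dose_times: np.ndarray
    amounts: np.ndarray


def _prepare_subjects(ds: TrialDataset) -> list[_SubjectData]:
    out = []
    for s in ds.subjects:
        obs = ds.observations_for(s.id)
        doses = ds.doses_for(s.id)
        out.append(
            _SubjectData(
                sid=s.id,
                subject=s,
                times=np.array([r.time for r in obs]),
                y=np.array([r.dv for r in obs]),
                dose_times=np.array([d.time for d in doses]),
                amounts=np.array([d.amount for d in doses]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# parameter packing


class _Packing:
    """Maps a PopulationModel to and from a flat unconstrained vector.

    Layout: log typical values (6), covariate exponents (raw), then the
    omega block, then log residual SDs.  A diagonal omega packs as log
    omega^2 per IIV parameter; a non-diagonal omega (``spec.omega_corr``
    set) packs the lower Cholesky factor of the full matrix, log on the
    diagonal and raw off-diagonal.
    """

    def __init__(self, spec: PopulationModel, fix_typical: tuple = ()):
        self.spec = spec
        self.fix_typical = tuple(fix_typical)
        self.free_typical = [p for p in STRUCTURAL_PARAMS if p not in fix_typical]
        self.eta_params = spec.eta_params
        self.diagonal_omega = spec.omega_corr is None
        self.sigma_kind = spec.sigma.kind
        self.n_sigma = 2 if self.sigma_kind == "combined" else 1
        if self.diagonal_omega:
            omega_labels = [f"omega2_{p}" for p in self.eta_params]
        else:
            omega_labels = [
                f"omega_chol_{self.eta_params[i]}_{self.eta_params[j]}"
                for i in range(len(self.eta_params))
                for j in range(i + 1)
            ]
        self.labels: list[str] = (
            [f"tv_{p}" for p in self.free_typical]
            + [f"beta_{e.covariate}_{e.parameter}" for e in spec.effects]
            + omega_labels
            + (
                ["sigma_add", "sigma_prop"]
                if self.sigma_kind == "combined"
                else ["sigma_add" if self.sigma_kind == "additive" else "sigma_prop"]
            )
        )
        self.n = len(self.labels)

    def pack(self, spec: PopulationModel) -> np.ndarray:
        x = [np.log(spec.typical[p]) for p in self.free_typical]
        x += [e.exponent for e in spec.effects]
        if self.diagonal_omega:
            x += [np.log(max(spec.iiv[p], 1e-8)) for p in self.eta_params]
        else:
            chol = np.linalg.cholesky(spec.omega_matrix())
            for i in range(len(self.eta_params)):
                for j in range(i + 1):
                    x.append(np.log(chol[i, i]) if i == j else chol[i, j])
        if self.sigma_kind == "combined":
            x += [np.log(spec.sigma.add_sd), np.log(spec.sigma.prop_sd)]
        elif self.sigma_kind == "additive":
            x += [np.log(spec.sigma.add_sd)]
        else:
            x += [np.log(spec.sigma.prop_sd)]
        return np.array(x)

    @staticmethod
    def _exp(v):
        # clip so that a wild line-search excursion stays finite/positive
        return float(np.exp(np.clip(v, -60.0, 60.0)))

    def unpack(self, x: np.ndarray) -> PopulationModel:
        spec = self.spec
        i = 0
        typical = dict(spec.typical)
        for p in self.free_typical:
            typical[p] = self._exp(x[i])
            i += 1
        effects = []
        for e in spec.effects:
            effects.append(
                CovariateEffect(e.parameter, e.covariate, float(x[i]), e.reference)
            )
            i += 1
        q = len(self.eta_params)
        if self.diagonal_omega:
            iiv = {}
            for p in self.eta_params:
                iiv[p] = self._exp(x[i])
                i += 1
            omega_corr = None
        else:
            chol = np.zeros((q, q))
            for a in range(q):
                for b in range(a + 1):
                    chol[a, b] = self._exp(x[i]) if a == b else x[i]
                    i += 1
            omega = chol @ chol.T
            sd = np.sqrt(np.diag(omega))
            iiv = dict(zip(self.eta_params, np.diag(omega)))
            omega_corr = omega / np.outer(sd, sd)
        if self.sigma_kind == "combined":
            sigma = ResidualModel(
                "combined", add_sd=self._exp(x[i]), prop_sd=self._exp(x[i + 1])
            )
        elif self.sigma_kind == "additive":
            sigma = ResidualModel("additive", add_sd=self._exp(x[i]))
        else:
            sigma = ResidualModel("proportional", prop_sd=self._exp(x[i]))
        return PopulationModel(
            typical=typical,
            effects=effects,
            iiv=iiv,
            omega_corr=omega_corr,
            sigma=sigma,
        )

    def natural_scale(self, x: np.ndarray, se: np.ndarray):
        """Estimates and SEs on the reporting scale (delta method).

        Covariate exponents and off-diagonal Cholesky entries are already
        on their natural (unconstrained) scale; everything else is
        log-parameterised.
        """
        est, nat_se = [], []
        for j, lab in enumerate(self.labels):
            raw = lab.startswith("beta_")
            if lab.startswith("omega_chol_"):
                a, b = lab[len("omega_chol_"):].split("_", 1)
                raw = a != b
            if raw:
                est.append(x[j])
                nat_se.append(se[j])
            else:
                v = np.exp(x[j])
                est.append(v)
                nat_se.append(se[j] * v)
        return np.array(est), np.array(nat_se)


# ---------------------------------------------------------------------------
# likelihood


def _variance(pred, sigma: ResidualModel):
    return sigma.variance(np.maximum(pred, _PRED_FLOOR))


def _dv_dpred(pred, sigma: ResidualModel):
    pred = np.maximum(pred, _PRED_FLOOR)
    if sigma.kind == "additive":
        return np.zeros_like(pred)
    return 2.0 * sigma.prop_sd**2 * pred


def _subject_base_params(spec: PopulationModel, subj) -> np.ndarray:
    vals = np.array([spec.typical[p] for p in STRUCTURAL_PARAMS])
    for eff in spec.effects:
        vals[_PARAM_INDEX[eff.parameter]] *= eff.factor(
            subj.covariate(eff.covariate)
        )
    return vals


def _subject_ofv(sd: _SubjectData, base, eta_idx, omega_inv, logdet_omega,
                 sigma: ResidualModel, eta0: np.ndarray):
    """FOCE contribution of one subject; returns (ofv_j, eta_mode)."""
    q = len(eta_idx)
    n = len(sd.y)
    if n == 0:
        return 0.0, eta0

    def conc_for(etas):
        # etas: (m, q) -> predicted concentrations (m, n); clipping keeps
        # wild line-search excursions finite
        theta = np.tile(base, (len(etas), 1))
        theta[:, eta_idx] *= np.exp(np.clip(etas, -40.0, 40.0))
        return concentration_batch(theta, sd.dose_times, sd.amounts, sd.times)

    if q == 0:
        f = conc_for(np.zeros((1, 0)))[0]
        r = sd.y - f
        v = _variance(f, sigma)
        return float(np.sum(r * r / v + np.log(2 * np.pi * v))), eta0

    def g_of(eta):
        f = conc_for(eta[None, :])[0]
        r = sd.y - f
        v = _variance(f, sigma)
        g = float(np.sum(r * r / v + np.log(v)) + eta @ omega_inv @ eta)
        if not np.isfinite(g):
            g = np.inf
        return g, f, v, r

    eta = eta0.copy()
    g, f, v, r = g_of(eta)
    h = 1e-5
    J = np.empty((n, q))

    def try_step(step, g, f, v, r, eta):
        t = 1.0
        for _ in range(14):
            g_new, f_new, v_new, r_new = g_of(eta + t * step)
            if g_new < g - 1e-12:
                return eta + t * step, g_new, f_new, v_new, r_new, t
            t *= 0.5
        return eta, g, f, v, r, 0.0

    for _ in range(150):
        # value + forward-difference Jacobian in one batched call
        pts = np.vstack([eta[None, :] + h * np.eye(q)])
        fp = conc_for(pts)
        for k in range(q):
            J[:, k] = (fp[k] - f) / h
        w = _dv_dpred(f, sigma)
        grad = J.T @ (-2.0 * r / v - r * r * w / v**2 + w / v) + 2.0 * omega_inv @ eta
        H = 2.0 * (J.T @ (J / v[:, None])) + 2.0 * omega_inv
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -grad / np.linalg.norm(grad + 1e-300)
        if not np.all(np.isfinite(step)):
            break
        # quadratic-model decrease; at the mode skip the doomed line search
        predicted = -0.5 * float(grad @ step)
        if predicted < 1e-8:
            break
        eta, g, f, v, r, t = try_step(step, g, f, v, r, eta)
        if t == 0.0:
            # Gauss-Newton direction failed (non-smooth kink, e.g. the lag
            # crossing an observation time); fall back to scaled descent
            scale = np.sqrt(np.max(np.diag(H))) + 1e-300
            eta, g, f, v, r, t = try_step(-grad / scale, g, f, v, r, eta)
            if t == 0.0:
                break
        if np.max(np.abs(t * step)) < 1e-9:
            break

    # Laplace/Gauss-Newton correction at the mode
    pts = eta[None, :] + h * np.eye(q)
    fp = conc_for(pts)
    for k in range(q):
        J[:, k] = (fp[k] - f) / h
    H_half = J.T @ (J / v[:, None]) + omega_inv
    sign, logdet_h = np.linalg.slogdet(H_half)
    if sign <= 0:
        logdet_h = np.log(np.maximum(np.linalg.eigvalsh(H_half), 1e-10)).sum()
    ofv_j = g + n * np.log(2 * np.pi) + logdet_omega + logdet_h
    return float(ofv_j), eta


def objective(
    spec: PopulationModel,
    ds: TrialDataset,
    eta_cache: dict | None = None,
    subjects: list[_SubjectData] | None = None,
) -> float:
    """FOCE objective function value (-2 x approximate log-likelihood).

    ``eta_cache`` (sid -> eta vector) is updated in place and warm-starts
    the per-subject inner optimisations across calls.
    """
    if subjects is None:
        subjects = _prepare_subjects(ds)
    q = len(spec.eta_params)
    eta_idx = np.array([_PARAM_INDEX[p] for p in spec.eta_params], dtype=int)
    if q:
        omega = spec.omega_matrix()
        # a non-PSD or numerically singular omega proposal is rejected with
        # a finite penalty (np.linalg.inv does not reliably raise on exact
        # singularity)
        eig = np.linalg.eigvalsh(omega)
        if eig.min() <= 1e-10 * max(eig.max(), 1e-300):
            return 1e12
        omega_inv = np.linalg.inv(omega)
        logdet_omega = float(np.sum(np.log(eig)))
    else:
        omega_inv = np.zeros((0, 0))
        logdet_omega = 0.0
    total = 0.0
    for sd in subjects:
        eta0 = (
            eta_cache.get(sd.sid, np.zeros(q)) if eta_cache is not None else np.zeros(q)
        )
        if eta0.shape != (q,):
            eta0 = np.zeros(q)
        base = _subject_base_params(spec, sd.subject)
        ofv_j, eta = _subject_ofv(
            sd, base, eta_idx, omega_inv, logdet_omega, spec.sigma, eta0
        )
        if eta_cache is not None:
            eta_cache[sd.sid] = eta
        total += ofv_j
    return total


def nca_informed_start(
    spec: PopulationModel, ds: TrialDataset, single_dose_window: float = 96.0
) -> PopulationModel:
    """Starting specification from non-compartmental heuristics.

    Typical CL from the median of per-subject dose/AUC0-inf on the
    single-dose profiles, typical V from the median of dose/Cmax;
    inter-compartmental parameters start at half those values, Ka at 1/h,
    Tlag at 0.5 h.  Covariate exponents start at zero, omega^2 at 0.1 and
    the proportional residual SD at 0.2.
    """
    from .nca import nca_profile

    cls, vs = [], []
    for s in ds.subjects:
        obs = [r for r in ds.observations_for(s.id) if r.time <= single_dose_window]
        if len(obs) < 3:
            continue
        t = np.array([r.time for r in obs])
        c = np.array([r.dv for r in obs])
        order = np.argsort(t)
        try:
            res = nca_profile(t[order], c[order], s.dose_mg)
        except ValueError:
            continue
        if res.cl_f is not None:
            cls.append(res.cl_f)
        vs.append(1000.0 * s.dose_mg / res.cmax)  # mg / (ng/mL) -> L
    cl0 = float(np.median(cls)) if cls else 1.0
    v0 = float(np.median(vs)) if vs else 20.0
    start = spec.copy()
    start.typical = {
        "ka": 1.0,
        "tlag": 0.5,
        "v": v0,
        "v2": v0,
        "cl": cl0,
        "cl2": cl0 / 2.0,
    }
    start.effects = [
        CovariateEffect(e.parameter, e.covariate, 0.0, e.reference)
        for e in spec.effects
    ]
    start.iiv = {p: 0.1 for p in spec.iiv}
    if spec.sigma.kind == "proportional":
        start.sigma = ResidualModel("proportional", prop_sd=0.2)
    elif spec.sigma.kind == "additive":
        start.sigma = ResidualModel("additive", add_sd=max(0.05 * v0, 1.0))
    else:
        start.sigma = ResidualModel("combined", prop_sd=0.2, add_sd=1.0)
    return start


# ---------------------------------------------------------------------------
# results object


@dataclass
class ComparisonResult:
    """Nested-model comparison at a chi-square threshold."""

    delta_ofv: float
    df: int
    threshold: float
    accept: bool

    def __str__(self) -> str:
        verdict = "accept extension" if self.accept else "keep base"
        return (
            f"dOFV = {self.delta_ofv:.2f} (df={self.df}, "
            f"threshold {self.threshold}): {verdict}"
        )


def compare(base: "PopPKResults", extended: "PopPKResults",
            threshold: float = 3.84) -> ComparisonResult:
    """Decide whether an extended (nested) model is superior.

    The extension is accepted when the OFV drops by more than ``threshold``
    (3.84 is the chi-square df=1 quantile at p=0.05; 6.64 at p=0.01).
    """
    base_ofv = base.ofv if hasattr(base, "ofv") else float(base)
    ext_ofv = extended.ofv if hasattr(extended, "ofv") else float(extended)
    df = 1
    if hasattr(base, "n_params") and hasattr(extended, "n_params"):
        df = max(extended.n_params - base.n_params, 1)
    delta = base_ofv - ext_ofv
    return ComparisonResult(
        delta_ofv=delta, df=df, threshold=threshold, accept=delta > threshold
    )


@dataclass
class PopPKResults:
    """Estimation results: estimates, uncertainty, fit criteria, etas."""

    model: "PopPKModel"
    spec: PopulationModel  # fitted specification
    params: pd.Series  # natural-scale estimates by label
    rse_percent: pd.Series | None
    ofv: float
    n_obs: int
    n_params: int
    etas: dict  # sid -> eta vector over spec.eta_params
    converged: bool
    message: str = ""
    n_function_evals: int = 0

    @property
    def aic(self) -> float:
        return self.ofv + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.ofv + self.n_params * np.log(self.n_obs)

    def eta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {sid: pd.Series(e, index=self.spec.eta_params) for sid, e in self.etas.items()}
        ).T

    # diagnostics live in poppk.diagnostics; thin delegation keeps the
    # results object the single entry point
    def gof(self):
        from .diagnostics import gof

        return gof(self)

    def vpc(self, n: int = 1000, seed: int = 0, bins=None):
        from .diagnostics import vpc

        return vpc(self.spec, self.model.dataset, n=n, seed=seed, bins=bins)

    def npde(self, n: int = 1000, seed: int = 0):
        from .diagnostics import npde

        return npde(self.spec, self.model.dataset, n=n, seed=seed)

    def bootstrap(self, n: int = 1000, seed: int = 0, **kw):
        from .diagnostics import bootstrap

        return bootstrap(self, n=n, seed=seed, **kw)

    def summary(self) -> str:
        lines = [
            "Population PK fit (FOCE with interaction)",
            "=" * 58,
            f"n subjects: {len(self.model.dataset.subjects):4d}"
            f"    n observations: {self.n_obs}",
            f"OFV: {self.ofv:.2f}    AIC: {self.aic:.2f}    BIC: {self.bic:.2f}",
            f"converged: {self.converged}  ({self.message})",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>12}{'RSE%':>10}",
        ]
        for lab in self.params.index:
            rse = (
                f"{self.rse_percent[lab]:.1f}"
                if self.rse_percent is not None and np.isfinite(self.rse_percent[lab])
                else "-"
            )
            lines.append(f"{lab:<22}{self.params[lab]:>12.4g}{rse:>10}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": {k: float(v) for k, v in self.params.items()},
            "rse_percent": (
                {k: float(v) for k, v in self.rse_percent.items()}
                if self.rse_percent is not None
                else None
            ),
            "ofv": float(self.ofv),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "etas": {k: np.asarray(v).tolist() for k, v in self.etas.items()},
        }


# ---------------------------------------------------------------------------
# model object


class PopPKModel:
    """Nonlinear mixed-effects PK model bound to a dataset.

    Parameters
    ----------
    dataset : TrialDataset
    spec : PopulationModel
        Starting specification; its typical values seed the search unless
        ``fit(start=...)`` overrides them.
    fix_typical : tuple of str
        Structural parameters whose typical values are held at the
        specification value (not estimated).
    """

    def __init__(self, dataset: TrialDataset, spec: PopulationModel,
                 fix_typical: tuple = ()):
        for s in dataset.subjects:
            if not dataset.observations_for(s.id):
                raise ValueError(
                    f"subject {s.id} has no usable (non-BLQ) observations"
                )
        self.dataset = dataset
        self.spec = spec
        self.packing = _Packing(spec, fix_typical=fix_typical)
        self._subjects = _prepare_subjects(dataset)
        self.n_obs = sum(len(sd.y) for sd in self._subjects)
        if self.packing.n >= len(dataset.subjects) + self.n_obs:
            import warnings

            warnings.warn(
                "model has as many parameters as data points; estimates "
                "will not be identifiable",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: PopulationModel, **kw):
        from .data import from_frame

        return cls(from_frame(df), spec, **kw)

    def objective_at(self, spec: PopulationModel | None = None,
                     eta_cache: dict | None = None) -> float:
        return objective(
            spec or self.spec, self.dataset, eta_cache=eta_cache,
            subjects=self._subjects,
        )

    #: coordinate offsets (log scale) used by the between-round basin probe
    _PROBE_DELTAS = (-0.25, -0.05, 0.05, 0.25)

    def fit(self, start: PopulationModel | None = None, compute_rse: bool = True,
            maxiter: int = 500, ftol: float = 1e-9, restarts: int = 3) -> PopPKResults:
        """Maximise the FOCE approximate likelihood from ``start``.

        The FOCE surface carries small discontinuities where a subject's
        conditional eta mode jumps basins (a lag-time crossing an
        observation time); the outer search therefore uses a coarse
        finite-difference step, and between L-BFGS-B rounds a coordinate
        probe looks for a lower basin to restart from (up to ``restarts``
        rounds; ``restarts=1`` disables probing).  Non-convergence is
        reported through ``converged``/``message`` on the results object
        with the best point found, never silently.
        """
        packing = self.packing
        x0 = packing.pack(start or self.spec)
        eta_cache: dict = {}
        n_evals = [0]

        def fun(x):
            n_evals[0] += 1
            spec = packing.unpack(x)
            val = objective(spec, self.dataset, eta_cache=eta_cache,
                            subjects=self._subjects)
            if not np.isfinite(val):
                return 1e12
            return val

        res = None
        for round_no in range(max(restarts, 1)):
            cur = optimize.minimize(
                fun,
                x0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-3,
                         "eps": 3e-3, "maxcor": 25},
            )
            if res is None or cur.fun < res.fun:
                res = cur
            if round_no == max(restarts, 1) - 1:
                break
            # probe each coordinate for a lower basin
            probe_f, probe_x = res.fun, None
            for i in range(packing.n):
                for d in self._PROBE_DELTAS:
                    x = res.x.copy()
                    x[i] += d
                    fx = fun(x)
                    if fx < probe_f - 0.5:
                        probe_f, probe_x = fx, x
            if probe_x is None:
                break
            x0 = probe_x
        spec_hat = packing.unpack(res.x)
        # empirical-Bayes etas at the final point
        final_cache: dict = {}
        ofv = objective(spec_hat, self.dataset, eta_cache=final_cache,
                        subjects=self._subjects)

        rse = None
        se_packed = None
        if compute_rse:
            se_packed = self._standard_errors(fun, res.x)
        est_nat, se_nat = packing.natural_scale(
            res.x, se_packed if se_packed is not None else np.full(packing.n, np.nan)
        )
        params = pd.Series(est_nat, index=packing.labels)
        if compute_rse and se_packed is not None:
            rse = pd.Series(
                100.0 * se_nat / np.abs(est_nat), index=packing.labels
            )
        return PopPKResults(
            model=self,
            spec=spec_hat,
            params=params,
            rse_percent=rse,
            ofv=float(ofv),
            n_obs=self.n_obs,
            n_params=packing.n,
            etas=final_cache,
            converged=bool(res.success),
            message=str(res.message),
            n_function_evals=n_evals[0],
        )

    @staticmethod
    def _standard_errors(fun, x):
        """SEs from the numerical Hessian of the OFV (cov = 2 H^-1)."""
        from statsmodels.tools.numdiff import approx_hess1

        try:
            hess = approx_hess1(x, fun)
            cov = 2.0 * np.linalg.inv(hess)
            diag = np.diag(cov)
            if np.any(diag < 0):
                return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
            return np.sqrt(diag)
        except np.linalg.LinAlgError:
            return None
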