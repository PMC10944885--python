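"""Stepwise covariate modelling: collinearity pre-screen, forward
inclusion, backward elimination.

The pre-screen computes pairwise Pearson correlations across the covariate
table and, whenever |r| > 0.5 with p < 0.05, retains only one member of the
pair — the one ranking higher under a caller-supplied univariate score
(conventionally the OFV drop when the covariate is tested alone on CL/F),
falling back to a fixed priority order.  Survivors become candidates for
the stepwise search: forward steps add the best candidate
parameter-covariate pair while the OFV falls by more than 3.84 (chi-square
df=1, p<0.05); backward steps delete effects whose removal raises the OFV
by at most 6.64 (p<0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialDataset
from .estimation import PopPKModel
from .model import CovariateEffect, PopulationModel

__all__ = [
    "ScreenReport",
    "StepEntry",
    "StepTrace",
    "prescreen",
    "univariate_ofv_drops",
    "forward_step",
    "backward_step",
    "run_stepwise",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

FORWARD_THRESHOLD = 3.84  # chi-square(1) at p = 0.05
BACKWARD_THRESHOLD = 6.64  # chi-square(1) at p = 0.01

#: Parameters a candidate covariate is tested on during the stepwise search.
SEARCH_PARAMETERS = ("cl", "v", "cl2", "v2")

#: Fallback priority when no univariate ranking is supplied (cohort-table
#: ordering of the continuous covariates).
_DEFAULT_PRIORITY = (
    "AGE", "HT", "WT", "BMI", "BSA", "LBW", "BFP", "IBW", "ADJWT",
    "BUN", "LDH", "CR", "CLCR", "ADJCLCR", "TBIL", "ALT", "AST", "ALP",
)


@dataclass
class ScreenReport:
    correlation: pd.DataFrame
    p_values: pd.DataFrame
    excluded: dict  # covariate -> retained partner
    candidates: list
    dropped_constant: list = field(default_factory=list)


@dataclass
class StepEntry:
    action: str  # "add" | "remove" | "none"
    parameter: str | None
    covariate: str | None
    ofv_before: float
    ofv_after: float
    accepted: bool

    @property
    def delta_ofv(self) -> float:
        return self.ofv_after - self.ofv_before


@dataclass
class StepTrace:
    entries: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.entries, start=1):
            rows.append(
                {
                    "step": i,
                    "action": e.action,
                    "effect": (
                        f"{e.parameter}-{e.covariate}" if e.covariate else "none"
                    ),
                    "OFV_before": e.ofv_before,
                    "OFV_after": e.ofv_after,
                    "dOFV": e.delta_ofv,
                    "accepted": e.accepted,
                }
            )
        return pd.DataFrame(rows)


def prescreen(
    covariate_table: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    rank: dict | None = None,
) -> ScreenReport:
    """Collinearity pre-screen over a subjects x covariates table.

    ``rank`` maps covariate name to a univariate score (higher retained
    first); unranked covariates fall back to the cohort-table priority
    order.  Zero-variance covariates are dropped with a warning entry.
    """
    if len(covariate_table) < 3:
        raise ValueError("need at least 3 subjects for a correlation screen")
    table = covariate_table.select_dtypes(include=[np.number]).copy()
    dropped_constant = [c for c in table.columns if table[c].std(ddof=1) == 0]
    table = table.drop(columns=dropped_constant)
    names = list(table.columns)
    k = len(names)
    corr = pd.DataFrame(np.eye(k), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(table.iloc[:, i], table.iloc[:, j])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p

    def sort_key(name):
        score = -(rank or {}).get(name, -np.inf)
        prio = (
            _DEFAULT_PRIORITY.index(name)
            if name in _DEFAULT_PRIORITY
            else len(_DEFAULT_PRIORITY)
        )
        return (score, prio, name)

    ordered = sorted(names, key=sort_key)
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for name in ordered:
        clash = next(
            (
                kept
                for kept in retained
                if abs(corr.loc[name, kept]) > r_threshold
                and pval.loc[name, kept] < p_threshold
            ),
            None,
        )
        if clash is None:
            retained.append(name)
        else:
            excluded[name] = clash
    candidates = [n for n in names if n in retained]
    return ScreenReport(
        correlation=corr,
        p_values=pval,
        excluded=excluded,
        candidates=candidates,
        dropped_constant=dropped_constant,
    )


def _covariate_table(ds: TrialDataset, covariates=None) -> pd.DataFrame:
    rows = {s.id: dict(s.covariates) for s in ds.subjects}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if covariates is not None:
        table = table[list(covariates)]
    return table


def _fit_ofv(spec: PopulationModel, ds: TrialDataset, **fit_kw) -> float:
    model = PopPKModel(ds, spec)
    res = model.fit(compute_rse=False, **fit_kw)
    return res.ofv, res.spec


def _with_effect(spec, parameter, covariate, reference, exponent=0.0):
    new = spec.copy()
    new.effects = list(new.effects) + [
        CovariateEffect(parameter, covariate, exponent, reference)
    ]
    return new


def univariate_ofv_drops(
    spec: PopulationModel,
    ds: TrialDataset,
    covariates,
    parameter: str = "cl",
    base_ofv: float | None = None,
    **fit_kw,
) -> dict:
    """OFV drop when each covariate is tested alone on ``parameter``.

    Used to rank collinear covariates in the pre-screen.
    """
    if base_ofv is None:
        base_ofv, _ = _fit_ofv(spec, ds, **fit_kw)
    table = _covariate_table(ds, covariates)
    drops = {}
    for name in covariates:
        ref = float(table[name].median())
        trial_spec = _with_effect(spec, parameter, name, ref)
        ofv, _ = _fit_ofv(trial_spec, ds, **fit_kw)
        drops[name] = base_ofv - ofv
    return drops


def forward_step(
    spec: PopulationModel,
    ds: TrialDataset,
    candidates,
    base_ofv: float | None = None,
    threshold: float = FORWARD_THRESHOLD,
    search_parameters=SEARCH_PARAMETERS,
    **fit_kw,
):
    """One forward-inclusion step.

    ``candidates`` is a list of covariate names or explicit (parameter,
    covariate) pairs; names are expanded over ``search_parameters``.  Fits
    every extension and adds the pair with the largest OFV decline if it
    exceeds ``threshold``; otherwise returns a no-op entry.

    Returns ``(entry, new_spec)``; ``new_spec`` carries the refitted
    estimates when a pair is accepted, else the input spec.
    """
    if base_ofv is None:
        base_ofv, spec = _fit_ofv(spec, ds, **fit_kw)
    pairs = []
    present = {(e.parameter, e.covariate) for e in spec.effects}
    for cand in candidates:
        expanded = (
            [(p, cand) for p in search_parameters] if isinstance(cand, str) else [cand]
        )
        pairs.extend(pc for pc in expanded if pc not in present)
    if not pairs:
        return (
            StepEntry("none", None, None, base_ofv, base_ofv, accepted=False),
            spec,
        )
    table = _covariate_table(ds)
    best = None
    for parameter, covariate in pairs:
        ref = float(table[covariate].median())
        trial_spec = _with_effect(spec, parameter, covariate, ref)
        ofv, fitted = _fit_ofv(trial_spec, ds, **fit_kw)
        if best is None or ofv < best[0]:
            best = (ofv, parameter, covariate, fitted)
    ofv, parameter, covariate, fitted = best
    accepted = (base_ofv - ofv) > threshold
    entry = StepEntry(
        "add" if accepted else "none",
        parameter if accepted else None,
        covariate if accepted else None,
        base_ofv,
        ofv if accepted else base_ofv,
        accepted=accepted,
    )
    return entry, (fitted if accepted else spec)


def backward_step(
    spec: PopulationModel,
    ds: TrialDataset,
    base_ofv: float | None = None,
    threshold: float = BACKWARD_THRESHOLD,
    **fit_kw,
):
    """One backward-elimination step.

    Refits the model with each covariate effect deleted in turn and removes
    the effect whose deletion raises the OFV least, provided that rise is
    at most ``threshold``; otherwise every effect is retained.
    """
    if not spec.effects:
        raise ValueError("backward step requires at least one covariate effect")
    if base_ofv is None:
        base_ofv, spec = _fit_ofv(spec, ds, **fit_kw)
    best = None
    for i, eff in enumerate(spec.effects):
        reduced = spec.copy()
        reduced.effects = [e for j, e in enumerate(spec.effects) if j != i]
        ofv, fitted = _fit_ofv(reduced, ds, **fit_kw)
        if best is None or ofv < best[0]:
            best = (ofv, eff, fitted)
    ofv, eff, fitted = best
    rise = ofv - base_ofv
    accepted = rise <= threshold
    entry = StepEntry(
        "remove" if accepted else "none",
        eff.parameter if accepted else None,
        eff.covariate if accepted else None,
        base_ofv,
        ofv if accepted else base_ofv,
        accepted=accepted,
    )
    return entry, (fitted if accepted else spec)


def run_stepwise(
    spec: PopulationModel,
    ds: TrialDataset,
    candidates,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    search_parameters=SEARCH_PARAMETERS,
    max_steps: int = 20,
    **fit_kw,
):
    """Full forward phase then full backward phase.

    Returns ``(final_spec, StepTrace)``; the trace records every accepted
    step plus the terminating no-op of each phase.
    """
    trace = StepTrace()
    ofv, spec = _fit_ofv(spec, ds, **fit_kw)
    remaining = list(candidates)
    for _ in range(max_steps):
        entry, spec = forward_step(
            spec, ds, remaining, base_ofv=ofv,
            threshold=forward_threshold,
            search_parameters=search_parameters, **fit_kw,
        )
        trace.entries.append(entry)
        if not entry.accepted:
            break
        ofv = entry.ofv_after
    for _ in range(max_steps):
        if not spec.effects:
            break
        entry, spec = backward_step(
            spec, ds, base_ofv=ofv, threshold=backward_threshold, **fit_kw
        )
        trace.entries.append(entry)
        if not entry.accepted:
            break
        ofv = entry.ofv_after
    return spec, trace
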