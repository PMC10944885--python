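"""Event-level trial data: dose events, concentration observations, covariates.

The in-memory representation mirrors the NONMEM-style analysis dataset used
throughout the package: one row per event, where dose rows carry ``EVID=1``
and an amount (mg) and observation rows carry ``EVID=0`` and a measured
plasma concentration (ng/mL).  Covariates are baseline-only and constant
within subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "DoseEvent",
    "ConcentrationRecord",
    "TrialDataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "LLOQ_NG_ML",
]

#: Lower limit of quantification of the plasma assay (ng/mL); observations
#: below it are flagged BLQ and excluded from estimation.
LLOQ_NG_ML = 50.0

#: Dose strengths (mg) used in the dose-escalation design.
DOSE_LEVELS_MG = (100, 200, 300, 400, 500, 650, 900)


class DatasetFormatError(ValueError):
    """A file does not conform to the expected column layout."""


class DatasetValidationError(ValueError):
    """Parsed data violate a dataset invariant."""


@dataclass(frozen=True)
class Subject:
    """One enrolled patient: dose arm and baseline covariates."""

    id: str
    dose_mg: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise DatasetValidationError(f"subject {self.id}: dose_mg must be > 0")
        for name, value in self.covariates.items():
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise DatasetValidationError(
                    f"subject {self.id}: covariate {name} is not finite"
                )

    def covariate(self, name: str) -> float:
        try:
            return float(self.covariates[name])
        except KeyError:
            raise KeyError(
                f"subject {self.id} lacks required covariate {name!r}"
            ) from None


@dataclass(frozen=True)
class DoseEvent:
    """An oral dose: time (h since first dose) and amount (mg)."""

    subject_id: str
    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: dose time {self.time} < 0"
            )
        if self.amount <= 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: dose amount must be > 0"
            )


@dataclass(frozen=True)
class ConcentrationRecord:
    """One plasma concentration observation (DV, ng/mL)."""

    subject_id: str
    time: float
    dv: float
    is_blq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: observation time {self.time} < 0"
            )
        if not self.is_blq and self.dv < 0:
            raise DatasetValidationError(
                f"subject {self.subject_id}: negative DV at t={self.time}"
            )


@dataclass
class TrialDataset:
    """A full trial: subjects, dose events and concentration records.

    ``meta`` carries provenance (generator seed, source file, package
    version) and travels with every derived artifact.
    """

    subjects: list[Subject]
    doses: list[DoseEvent]
    observations: list[ConcentrationRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ids = {s.id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise DatasetValidationError("duplicate subject ids")
        for ev in self.doses:
            if ev.subject_id not in ids:
                raise DatasetValidationError(
                    f"dose event references unknown subject {ev.subject_id}"
                )
        for rec in self.observations:
            if rec.subject_id not in ids:
                raise DatasetValidationError(
                    f"observation references unknown subject {rec.subject_id}"
                )
        for sid in ids:
            times = [ev.time for ev in self.doses if ev.subject_id == sid]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise DatasetValidationError(
                    f"subject {sid}: dose times not strictly increasing"
                )
            obs_times = [r.time for r in self.observations if r.subject_id == sid]
            if len(obs_times) != len(set(obs_times)):
                raise DatasetValidationError(
                    f"subject {sid}: duplicate observation times"
                )

    # -- accessors ----------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def doses_for(self, sid: str) -> list[DoseEvent]:
        return [ev for ev in self.doses if ev.subject_id == sid]

    def observations_for(self, sid: str, include_blq: bool = False):
        return [
            r
            for r in self.observations
            if r.subject_id == sid and (include_blq or not r.is_blq)
        ]

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def to_frame(self) -> pd.DataFrame:
        """Event-level DataFrame with NONMEM-style columns.

        Row order is deterministic: subject (enrollment order), then time,
        with dose events preceding same-time observations; SEQ makes the
        within-time ordering explicit.
        """
        cov_names = sorted({k for s in self.subjects for k in s.covariates})
        rows = []
        for s in self.subjects:
            events = [(ev.time, 0, ev) for ev in self.doses_for(s.id)]
            events += [
                (r.time, 1, r)
                for r in self.observations
                if r.subject_id == s.id
            ]
            events.sort(key=lambda e: (e[0], e[1]))
            for seq, (t, kind, ev) in enumerate(events):
                row = {"ID": s.id, "TIME": t, "SEQ": seq}
                if kind == 0:
                    row.update(AMT=ev.amount, DV=np.nan, EVID=1, MDV=1, BLQ=0)
                else:
                    row.update(
                        AMT=0.0,
                        DV=ev.dv,
                        EVID=0,
                        MDV=int(ev.is_blq),
                        BLQ=int(ev.is_blq),
                    )
                row["DOSE"] = s.dose_mg
                for name in cov_names:
                    row[name] = s.covariates.get(name, np.nan)
                rows.append(row)
        columns = ["ID", "TIME", "SEQ", "AMT", "DV", "EVID", "MDV", "BLQ", "DOSE"]
        return pd.DataFrame(rows, columns=columns + cov_names)


_REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")
_RESERVED = {"ID", "TIME", "SEQ", "AMT", "DV", "EVID", "MDV", "BLQ", "DOSE"}


def from_frame(df: pd.DataFrame, meta: dict | None = None) -> TrialDataset:
    """Build a :class:`TrialDataset` from an event-level DataFrame."""
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing required column {col!r}")
    cov_names = [c for c in df.columns if c not in _RESERVED]
    subjects, doses, observations = [], [], []
    for sid, grp in df.groupby("ID", sort=False):
        sid = str(sid)
        if "SEQ" in grp.columns:
            grp = grp.sort_values(["TIME", "SEQ"], kind="stable")
        first = grp.iloc[0]
        dose_rows = grp[grp["EVID"] == 1]
        if "DOSE" in grp.columns and np.isfinite(first["DOSE"]):
            dose_mg = float(first["DOSE"])
        elif len(dose_rows):
            dose_mg = float(dose_rows["AMT"].iloc[0])
        else:
            raise DatasetValidationError(f"subject {sid}: no dose information")
        covs = {}
        for name in cov_names:
            val = pd.to_numeric(pd.Series([first[name]]), errors="coerce").iloc[0]
            if np.isfinite(val):
                covs[name] = float(val)
        subjects.append(Subject(id=sid, dose_mg=dose_mg, covariates=covs))
        prev_t = -np.inf
        for _, row in dose_rows.iterrows():
            t = float(row["TIME"])
            if t <= prev_t:
                raise DatasetValidationError(
                    f"subject {sid}: non-monotone dose times"
                )
            prev_t = t
            doses.append(DoseEvent(subject_id=sid, time=t, amount=float(row["AMT"])))
        for _, row in grp[grp["EVID"] == 0].iterrows():
            blq = bool(row.get("BLQ", 0)) or (
                np.isfinite(row["DV"]) and row["DV"] < LLOQ_NG_ML
            )
            observations.append(
                ConcentrationRecord(
                    subject_id=sid,
                    time=float(row["TIME"]),
                    dv=float(row["DV"]) if np.isfinite(row["DV"]) else 0.0,
                    is_blq=blq,
                )
            )
    return TrialDataset(subjects, doses, observations, meta=dict(meta or {}))


def read_dataset(path, rename: Mapping[str, str] | None = None) -> TrialDataset:
    """Read a NONMEM-style CSV into a :class:`TrialDataset`.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV with at least ID, TIME, AMT, DV, EVID columns; extra columns are
        treated as baseline covariates (taken from each subject's first row).
    rename : mapping, optional
        Maps file column names onto the expected names, e.g.
        ``{"SUBJ": "ID", "CONC": "DV"}``.
    """
    df = pd.read_csv(path)
    if rename:
        df = df.rename(columns=dict(rename))
    ds = from_frame(df, meta={"source": str(path)})
    return ds


def write_dataset(ds: TrialDataset, path) -> None:
    """Write the dataset as CSV in the same NONMEM-style dialect."""
    ds.to_frame().to_csv(path, index=False)
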