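"""Hierarchical population-PK model specification.

Maps a subject's covariates and random effects onto individual structural
parameters:

- typical values ``TVP`` per structural parameter;
- multiplicative power-law covariate effects normalised at the cohort
  median, ``(cov / reference)^theta``;
- lognormal inter-individual variability, ``P = TVP_cov * exp(eta)`` with
  ``eta ~ N(0, omega^2)`` on a subset of parameters;
- a residual (intra-individual) error model: proportional, additive or
  combined.

The published final model for oral ORIN1001 ships as a YAML fixture and is
returned by :func:`final_model`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .data import Subject
from .structural import PKParameters

__all__ = [
    "CovariateEffect",
    "ResidualModel",
    "PopulationModel",
    "final_model",
    "individual_typical_params",
    "individual_params",
    "residual_variance",
    "STRUCTURAL_PARAMS",
]

#: Canonical ordering of structural parameters.
STRUCTURAL_PARAMS = ("ka", "tlag", "v", "v2", "cl", "cl2")


@dataclass(frozen=True)
class CovariateEffect:
    """Power-law covariate effect, normalised at the cohort reference."""

    parameter: str
    covariate: str
    exponent: float
    reference: float

    def __post_init__(self) -> None:
        if self.parameter not in STRUCTURAL_PARAMS:
            raise ValueError(f"unknown structural parameter {self.parameter!r}")
        if self.reference <= 0:
            raise ValueError("covariate reference (median) must be > 0")

    def factor(self, value: float) -> float:
        if value <= 0:
            raise ValueError(
                f"covariate {self.covariate} must be > 0, got {value}"
            )
        return (value / self.reference) ** self.exponent


@dataclass(frozen=True)
class ResidualModel:
    """Residual error: var = add_sd^2 + (prop_sd * pred)^2."""

    kind: str = "proportional"  # proportional | additive | combined
    prop_sd: float = 0.0
    add_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual model kind {self.kind!r}")
        if self.kind in ("proportional", "combined") and self.prop_sd <= 0:
            raise ValueError("prop_sd must be > 0")
        if self.kind in ("additive", "combined") and self.add_sd <= 0:
            raise ValueError("add_sd must be > 0")

    def variance(self, pred):
        pred = np.asarray(pred, dtype=float)
        if self.kind == "proportional":
            return (self.prop_sd * pred) ** 2
        if self.kind == "additive":
            return np.full_like(pred, self.add_sd**2)
        return self.add_sd**2 + (self.prop_sd * pred) ** 2


@dataclass
class PopulationModel:
    """Complete model specification.

    Attributes
    ----------
    typical : dict
        Typical value per structural parameter (all six required).
    effects : list of CovariateEffect
    iiv : dict
        omega^2 variance per structural parameter carrying IIV (diagonal).
    omega_corr : ndarray, optional
        Correlation matrix over ``list(iiv)`` for a non-diagonal omega;
        ``None`` means diagonal.
    sigma : ResidualModel
    """

    typical: dict
    effects: list = field(default_factory=list)
    iiv: dict = field(default_factory=dict)
    omega_corr: np.ndarray | None = None
    sigma: ResidualModel = field(default_factory=lambda: ResidualModel(prop_sd=0.1))

    def __post_init__(self) -> None:
        for name in STRUCTURAL_PARAMS:
            if name not in self.typical:
                raise ValueError(f"typical value for {name!r} missing")
            if self.typical[name] <= 0:
                raise ValueError(f"typical value for {name!r} must be > 0")
        for name, var in self.iiv.items():
            if name not in STRUCTURAL_PARAMS:
                raise ValueError(f"IIV on unknown parameter {name!r}")
            if var < 0:
                raise ValueError("omega^2 must be >= 0")
        for eff in self.effects:
            if not isinstance(eff, CovariateEffect):
                raise TypeError("effects must be CovariateEffect instances")
        if self.omega_corr is not None:
            q = len(self.iiv)
            corr = np.asarray(self.omega_corr, dtype=float)
            if corr.shape != (q, q):
                raise ValueError("omega_corr shape must match len(iiv)")
            if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
                raise ValueError("omega_corr must be positive semidefinite")
            self.omega_corr = corr

    # -- omega --------------------------------------------------------------
    @property
    def eta_params(self) -> list[str]:
        return list(self.iiv)

    def omega_matrix(self) -> np.ndarray:
        """Full omega^2 covariance matrix over ``eta_params``."""
        sd = np.sqrt(np.array([self.iiv[p] for p in self.iiv]))
        if self.omega_corr is None:
            return np.diag(sd**2)
        return self.omega_corr * np.outer(sd, sd)

    # -- covariate machinery -------------------------------------------------
    def covariate_factor(self, parameter: str, subject: Subject) -> float:
        f = 1.0
        for eff in self.effects:
            if eff.parameter == parameter:
                f *= eff.factor(subject.covariate(eff.covariate))
        return f

    def required_covariates(self) -> list[str]:
        return sorted({eff.covariate for eff in self.effects})

    def copy(self) -> "PopulationModel":
        return copy.deepcopy(self)

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "typical": {k: float(v) for k, v in self.typical.items()},
            "effects": [
                {
                    "parameter": e.parameter,
                    "covariate": e.covariate,
                    "exponent": float(e.exponent),
                    "reference": float(e.reference),
                }
                for e in self.effects
            ],
            "iiv": {k: float(v) for k, v in self.iiv.items()},
            "sigma": {
                "kind": self.sigma.kind,
                "prop_sd": float(self.sigma.prop_sd),
                "add_sd": float(self.sigma.add_sd),
            },
        }
        if self.omega_corr is not None:
            d["omega_corr"] = np.asarray(self.omega_corr).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        sigma = d.get("sigma", {})
        return cls(
            typical=dict(d["typical"]),
            effects=[CovariateEffect(**e) for e in d.get("effects", [])],
            iiv=dict(d.get("iiv", {})),
            omega_corr=(
                np.asarray(d["omega_corr"], dtype=float)
                if "omega_corr" in d
                else None
            ),
            sigma=ResidualModel(
                kind=sigma.get("kind", "proportional"),
                prop_sd=sigma.get("prop_sd", 0.0),
                add_sd=sigma.get("add_sd", 0.0),
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def final_model() -> PopulationModel:
    """The published final ORIN1001 model (point estimates).

    Typical values Ka 0.58 1/h, Tlag 0.35 h, V/F 26.21 L, V2/F 26.60 L,
    CL/F 1.07 L/h, CL2/F 0.75 L/h; covariate exponents TBIL->CL/F -0.46,
    LBW->CL/F 1.11, LDH->V2/F 0.99, LBW->CL2/F 2.21 normalised at cohort
    medians TBIL 10.30 umol/L, LBW 45.13 kg, LDH 214 IU/L; diagonal omega^2
    {V/F 0.049, CL/F 0.067, Ka 0.534, Tlag 0.438}; proportional residual
    SD 0.197.
    """
    text = resources.files("poppk").joinpath("final_model.yaml").read_text()
    return PopulationModel.from_dict(yaml.safe_load(text))


def individual_typical_params(m: PopulationModel, s: Subject) -> PKParameters:
    """Covariate-adjusted typical parameters (eta = 0) for one subject."""
    values = {
        name: m.typical[name] * m.covariate_factor(name, s)
        for name in STRUCTURAL_PARAMS
    }
    return PKParameters(
        ka=values["ka"],
        tlag=values["tlag"],
        v=values["v"],
        v2=values["v2"],
        cl=values["cl"],
        cl2=values["cl2"],
    )


def individual_params(m: PopulationModel, s: Subject, eta) -> PKParameters:
    """Individual parameters with lognormal IIV, ``P = TVP_cov * exp(eta)``.

    ``eta`` is a vector indexed over ``m.eta_params`` (or a mapping);
    parameters without IIV pass through unchanged.
    """
    if isinstance(eta, dict):
        eta_map = dict(eta)
    else:
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (len(m.eta_params),):
            raise ValueError(
                f"eta must have length {len(m.eta_params)} (params {m.eta_params})"
            )
        eta_map = dict(zip(m.eta_params, eta))
    values = {}
    for name in STRUCTURAL_PARAMS:
        v = m.typical[name] * m.covariate_factor(name, s)
        if name in eta_map:
            v *= np.exp(eta_map[name])
        values[name] = v
    return PKParameters(
        ka=values["ka"],
        tlag=values["tlag"],
        v=values["v"],
        v2=values["v2"],
        cl=values["cl"],
        cl2=values["cl2"],
    )


def residual_variance(pred, sigma: ResidualModel):
    """Observation mean and variance under the residual error model."""
    pred = np.asarray(pred, dtype=float)
    return pred, sigma.variance(pred)
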