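"""Physiological and compound parameters of the minimal pig PBPK model.

:class:`ModelParameters` is the single source of truth for the ODE system:
it carries the published physiological constants (cardiac output, organ
flows and fractional volumes), the compound-specific constants of matrine
(gastric emptying, absorption, bioavailability, partition coefficients,
excretion rates, protein binding, renal clearance) and the body weight that
converts fractional quantities to absolute ones.

Fractional volumes are converted to litres and body weight to litres of
tissue under the unit-density convention (1 kg tissue or intestinal
content = 1 L), so concentrations in μg/L and μg/kg are interchangeable
throughout the package.

Two structural switches are exposed:

``f_mode``
    Where oral bioavailability F acts.  ``"systemic_scale"`` (default)
    keeps the intestinal mass balance exactly as published — the lumen
    loses the full absorptive flux k_a·A_int — while only F·k_a·A_int
    reaches blood and the remainder is routed to an "unabsorbed" sink.
    ``"dose_scale"`` instead loads the stomach depot with F·dose and lets
    the whole absorptive flux reach blood.
``pb_mode``
    How plasma protein binding Pb restricts distribution.
    ``"free_uptake"`` (default) lets only the free fraction (1−Pb) of the
    arterial concentration enter tissues and the renal route, which keeps
    the published blood equation verbatim *and* conserves mass.
    ``"verbatim"`` drives tissue uptake with the total arterial
    concentration as printed; that system creates mass at rate
    Q_tot·Ca·Pb and is exposed only for auditing via the mass-balance
    residual.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "optimized_parameters",
    "starting_parameters",
    "FITTABLE_PARAMETERS",
    "F_MODES",
    "PB_MODES",
]

F_MODES = ("systemic_scale", "dose_scale")
PB_MODES = ("free_uptake", "verbatim")

#: fields in [0, 1] by definition
_FRACTIONS = ("PCV", "Qc_l", "Qc_ot", "Vc_int", "Vc_l", "Vc_b", "Vc_ot", "F", "Pb")

#: numeric fields eligible for estimation (body weight is an experimental
#: covariate, not a model parameter)
FITTABLE_PARAMETERS = (
    "Qcar", "PCV", "Qc_l", "Qc_ot", "Vc_int", "Vc_l", "Vc_b", "Vc_ot",
    "k_st", "k_a", "F", "P_l", "P_ot", "k_e", "k_bi", "Pb", "Cl_renal",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates its physiological constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Parameter set for the four-compartment flow-limited model.

    Units: ``Qcar`` L/(h·kg BW); ``Cl_renal`` L/(h·kg BW); rate constants
    ``k_st``, ``k_a``, ``k_e``, ``k_bi`` 1/h; ``BW`` kg; the remaining
    fields are dimensionless fractions or partition coefficients.
    """

    Qcar: float
    PCV: float  # hematocrit; carried for completeness, enters no equation
    Qc_l: float
    Qc_ot: float
    Vc_int: float
    Vc_l: float
    Vc_b: float
    Vc_ot: float
    k_st: float
    k_a: float
    F: float
    P_l: float
    P_ot: float
    k_e: float
    k_bi: float
    Pb: float
    Cl_renal: float
    BW: float
    f_mode: str = "systemic_scale"
    pb_mode: str = "free_uptake"

    def __post_init__(self) -> None:
        for name in FITTABLE_PARAMETERS:
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ParameterError(f"{name} must be >= 0, got {value!r}")
        for name in _FRACTIONS:
            value = getattr(self, name)
            if value > 1.0:
                raise ParameterError(f"{name} is a fraction, got {value!r} > 1")
        if self.P_l <= 0 or self.P_ot <= 0:
            raise ParameterError("partition coefficients must be positive")
        if self.BW <= 0:
            raise ParameterError(f"BW must be positive, got {self.BW!r}")
        if abs(self.Qc_l + self.Qc_ot - 1.0) > 1e-9:
            raise ParameterError(
                f"Qc_l + Qc_ot must equal 1 (got {self.Qc_l + self.Qc_ot!r})"
            )
        vsum = self.Vc_int + self.Vc_l + self.Vc_b + self.Vc_ot
        if vsum > 1.0 + 1e-9:
            raise ParameterError(f"fractional volumes sum to {vsum!r} > 1")
        if self.f_mode not in F_MODES:
            raise ParameterError(f"f_mode must be one of {F_MODES}")
        if self.pb_mode not in PB_MODES:
            raise ParameterError(f"pb_mode must be one of {PB_MODES}")

    # ---- derived absolute quantities (unit density: kg BW ≡ L) ----

    @property
    def Q_l(self) -> float:
        """Hepatic blood flow, L/h."""
        return self.Qc_l * self.Qcar * self.BW

    @property
    def Q_ot(self) -> float:
        """Blood flow of the lumped other-organs compartment, L/h."""
        return self.Qc_ot * self.Qcar * self.BW

    @property
    def Q_tot(self) -> float:
        """Total arterial outflow Q_l + Q_ot = Qcar·BW, L/h."""
        return self.Q_l + self.Q_ot

    @property
    def V_int(self) -> float:
        """Intestinal-content volume, L."""
        return self.Vc_int * self.BW

    @property
    def V_l(self) -> float:
        return self.Vc_l * self.BW

    @property
    def V_b(self) -> float:
        return self.Vc_b * self.BW

    @property
    def V_ot(self) -> float:
        return self.Vc_ot * self.BW

    @property
    def fu(self) -> float:
        """Free (unbound) fraction in plasma, 1 − Pb."""
        return 1.0 - self.Pb

    # ---- convenience ----

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParameters":
        """Read a ``key: value`` parameter file (YAML subset)."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: expected a key: value mapping")
        return cls.from_dict(data)

    def to_config(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _load_packaged(name: str, BW: float, **overrides) -> ModelParameters:
    text = resources.files("matrine_pbpk").joinpath(f"data/{name}").read_text()
    data = yaml.safe_load(text)
    data["BW"] = BW
    data.update(overrides)
    return ModelParameters.from_dict(data)


def optimized_parameters(BW: float = 27.0, **overrides) -> ModelParameters:
    """The fitted parameter set for matrine in growing pigs.

    ``BW`` defaults to 27 kg, the mid-range of the single-dose study
    animals (24.3–31.1 kg).  Keyword overrides are applied on top, e.g.
    ``optimized_parameters(f_mode="dose_scale")``.
    """
    return _load_packaged("params_optimized.yaml", BW, **overrides)


def starting_parameters(BW: float = 27.0, **overrides) -> ModelParameters:
    """The literature-derived starting values used before optimization."""
    return _load_packaged("params_starting.yaml", BW, **overrides)
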