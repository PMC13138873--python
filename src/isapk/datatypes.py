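"""Shared domain types for the isavuconazole population-PK analysis.

All times are hours since a subject's first record, amounts in mg,
concentrations in mg/L, volumes in L and clearances in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

ORAL = "oral"
INTRAVENOUS = "intravenous"


@dataclass(frozen=True)
class DoseEvent:
    """A single drug administration.

    ``infusion_duration`` is 0 for oral doses and IV boluses; a positive
    value denotes a zero-order infusion of that length.
    """

    time: float
    amount: float
    route: str = ORAL
    infusion_duration: float = 0.0
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.infusion_duration < 0:
            raise ValueError("infusion_duration must be >= 0")
        if self.route not in (ORAL, INTRAVENOUS):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == ORAL and self.infusion_duration != 0:
            raise ValueError("oral doses cannot have an infusion duration")


@dataclass(frozen=True)
class Observation:
    """A measured concentration (DV); ``is_missing`` mirrors NONMEM's MDV."""

    time: float
    value: float
    is_missing: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not self.is_missing and not self.value > 0:
            raise ValueError("non-missing observation must have value > 0")


@dataclass(frozen=True)
class CovariateRecord:
    """Time-stamped covariates; ``None`` marks a value not quantified then."""

    time: float
    body_weight: Optional[float] = None
    height: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None  # "male" / "female"
    bmi: Optional[float] = None
    creatinine: Optional[float] = None
    egfr: Optional[float] = None
    total_bilirubin: Optional[float] = None
    albumin: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    alp: Optional[float] = None
    ggt: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("body_weight", "height", "age", "bmi", "creatinine",
                     "egfr", "total_bilirubin", "albumin", "alt", "ast",
                     "alp", "ggt"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"covariate {name} must be > 0 when present")
        if (self.bmi is not None and self.body_weight is not None
                and self.height is not None):
            implied = self.body_weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with weight/height^2 "
                    f"({implied:.2f})")


@dataclass
class OutcomeLabels:
    """Binary clinical outcomes with their evaluation times (hours)."""

    success: Optional[int] = None
    hepatotoxicity: Optional[int] = None
    discontinuation: Optional[int] = None
    evaluation_time: Optional[float] = None


@dataclass
class SubjectRecord:
    """One patient's dosing history, observations and covariates."""

    subject_id: str
    centre: int = 1
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    covariates: list[CovariateRecord] = field(default_factory=list)
    outcome_labels: Optional[OutcomeLabels] = None

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.time)
        self.observations = sorted(self.observations, key=lambda o: o.time)
        self.covariates = sorted(self.covariates, key=lambda c: c.time)

    @property
    def n_observed(self) -> int:
        return sum(1 for o in self.observations if not o.is_missing)


@dataclass
class PopulationModel:
    """Final-model population parameters.

    CL_i = tvcl * exp(eta_cl);  V_i = tvv * (BMI_i / bmi_ref)**bmi_power
    * exp(eta_v).  Interindividual variability is log-normal with SDs
    ``omega_cl`` / ``omega_v``; residual error is mixed
    (proportional ``sigma_prop`` + additive ``sigma_add``).
    """

    tvcl: float = 2.3        # L/h
    tvv: float = 523.0       # L
    ka: float = 2.5          # 1/h, fixed
    f_oral: float = 1.0      # oral bioavailability
    omega_cl: float = 0.37   # SD of log-normal IIV on CL
    omega_v: float = 0.34    # SD of log-normal IIV on V
    sigma_prop: float = 0.19  # proportional error SD (fraction)
    sigma_add: float = 0.73   # additive error SD (mg/L)
    bmi_ref: float = 25.0    # kg/m^2
    bmi_power: float = 1.0   # exponent on BMI/bmi_ref for V
    covariate_effects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("tvcl", "tvv", "ka", "bmi_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("omega_cl", "omega_v", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.f_oral <= 1:
            raise ValueError("f_oral must be in (0, 1]")

    def copy(self, **changes) -> "PopulationModel":
        return replace(self, **changes)


@dataclass(frozen=True)
class IndividualParameters:
    """Per-subject PK parameters after applying covariates and etas."""

    cl: float
    v: float
    ka: float
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError("cl, v, ka must all be positive")


@dataclass(frozen=True)
class ExposureMetrics:
    cmin_ss: float   # mg/L
    auc_tau: float   # mg*h/L
    tmax: float      # h
    half_life: float  # h
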