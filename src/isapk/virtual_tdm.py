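"""Virtual TDM study: steady-state cohort simulation and dose-adjustment strategies.

Ten thousand virtual patients receive 200 mg once daily at steady state.
BMI is uniform over the observed range, CL and V are log-normal around
the final-model typical values, and (CL, V) pairs implying implausible
half-lives are rejected and redrawn.  Each patient's true trough
(IPRED_TRUE) and AUC_TRUE = dose/CL are recorded together with one
noisy observed trough (C_min,RUV).

Dose adjustment targets the geometric mean of the therapeutic range on
the allowed dose grid {100, 200, 300, 400} mg, either directly
proportionally on C_min,RUV or on a MAP-Bayes estimate of C_min or AUC
derived from that single observation (MIPD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import PopulationModel
from .individual_bayes import map_from_single_trough
from .pk_core import cmin_ss_batch

CMIN_TARGET_RANGE = (2.5, 5.0)      # mg/L
AUC_TARGET_RANGE = (60.0, 233.0)    # mg*h/L
ALLOWED_DOSES = (100.0, 200.0, 300.0, 400.0)
DEFAULT_HALF_LIFE_BOUNDS = (40.0, 400.0)   # h
TAU = 24.0


@dataclass(frozen=True)
class VirtualPatient:
    bmi: float
    cl: float
    v: float
    half_life: float
    dose: float
    ipred_true_cmin: float
    auc_true: float
    cmin_ruv: float


@dataclass
class VirtualCohort:
    """Array-backed virtual population (columns as in VirtualPatient)."""

    bmi: np.ndarray
    cl: np.ndarray
    v: np.ndarray
    half_life: np.ndarray
    dose: np.ndarray
    ipred_true_cmin: np.ndarray
    auc_true: np.ndarray
    cmin_ruv: np.ndarray
    tau: float = TAU

    def __len__(self) -> int:
        return self.bmi.size

    def __getitem__(self, i: int) -> VirtualPatient:
        return VirtualPatient(*(float(getattr(self, f)[i]) for f in (
            "bmi", "cl", "v", "half_life", "dose",
            "ipred_true_cmin", "auc_true", "cmin_ruv")))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f: getattr(self, f) for f in (
            "bmi", "cl", "v", "half_life", "dose",
            "ipred_true_cmin", "auc_true", "cmin_ruv")})


@dataclass
class TdmStrategy:
    """A dose-adjustment policy.

    The dose changes only when the monitored estimate (noisy trough or
    Bayes-predicted metric) lies outside ``target_range`` — as in
    routine TDM practice, a measurement inside the therapeutic range
    prompts no intervention.  When adjusting, the proportional rule
    targets the geometric mean of the range on the allowed dose grid.
    """

    kind: str                                    # none / proportional_cmin /
    #                                              mipd_cmin / mipd_auc
    target_range: tuple = CMIN_TARGET_RANGE
    allowed_doses: tuple = ALLOWED_DOSES
    target_value: float = field(default=0.0)
    adjust_only_outside_range: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.target_range
        if not lo < hi:
            raise ValueError("target range must satisfy low < high")
        if not self.target_value:
            self.target_value = math.sqrt(lo * hi)


@dataclass
class AttainmentSummary:
    n: int
    pct_cmin_in_range: float
    pct_auc_in_range: float
    strategy: str


def simulate_cohort(
    n: int = 10000,
    pop: Optional[PopulationModel] = None,
    bmi_range: tuple = (12.0, 40.0),
    half_life_bounds: tuple = DEFAULT_HALF_LIFE_BOUNDS,
    dose: float = 200.0,
    tau: float = TAU,
    seed: int = 0,
) -> VirtualCohort:
    """Simulate ``n`` steady-state virtual patients on once-daily dosing.

    (CL, V) pairs whose implied half-life ln(2) V/CL falls outside
    ``half_life_bounds`` are rejected and redrawn; an overall rejection
    rate above 50% raises (implausible bounds).  Negative noisy troughs
    are redrawn too.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = half_life_bounds
    if not (0 < lo < hi):
        raise ValueError("half_life_bounds must be positive and ordered")
    pop = pop or PopulationModel()
    rng = np.random.default_rng(seed)

    bmi = np.empty(n)
    cl = np.empty(n)
    v = np.empty(n)
    filled = 0
    drawn = 0
    while filled < n:
        m = n - filled
        b = rng.uniform(bmi_range[0], bmi_range[1], m)
        eta_cl = rng.normal(0.0, pop.omega_cl, m) if pop.omega_cl > 0 \
            else np.zeros(m)
        eta_v = rng.normal(0.0, pop.omega_v, m) if pop.omega_v > 0 \
            else np.zeros(m)
        cl_m = pop.tvcl * np.exp(eta_cl)
        v_m = pop.tvv * (b / pop.bmi_ref) ** pop.bmi_power * np.exp(eta_v)
        t_half = math.log(2.0) * v_m / cl_m
        ok = (t_half >= lo) & (t_half <= hi)
        drawn += m
        k = int(ok.sum())
        bmi[filled:filled + k] = b[ok]
        cl[filled:filled + k] = cl_m[ok]
        v[filled:filled + k] = v_m[ok]
        filled += k
        if drawn >= 2 * n and filled < drawn // 2:
            raise ValueError(
                "half-life rejection rate above 50%; bounds implausible")

    half_life = math.log(2.0) * v / cl
    ipred_true = cmin_ss_batch(dose, tau, cl, v, pop.ka, pop.f_oral)
    auc_true = pop.f_oral * dose / cl

    cmin_ruv = np.full(n, -1.0)
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        m = int(todo.sum())
        eps_p = rng.normal(0.0, pop.sigma_prop, m)
        eps_a = rng.normal(0.0, pop.sigma_add, m)
        draw = ipred_true[todo] * (1.0 + eps_p) + eps_a
        cmin_ruv[todo] = draw
        todo = cmin_ruv <= 0

    return VirtualCohort(bmi=bmi, cl=cl, v=v, half_life=half_life,
                         dose=np.full(n, float(dose)),
                         ipred_true_cmin=ipred_true, auc_true=auc_true,
                         cmin_ruv=cmin_ruv, tau=tau)


def attainment(
    cohort: VirtualCohort,
    cmin_range: tuple = CMIN_TARGET_RANGE,
    auc_range: tuple = AUC_TARGET_RANGE,
    strategy: str = "none",
) -> AttainmentSummary:
    """Fractions of the cohort inside the therapeutic ranges (inclusive)."""
    for lo, hi in (cmin_range, auc_range):
        if not lo < hi:
            raise ValueError("range must satisfy low < high")
    c = cohort.ipred_true_cmin
    a = cohort.auc_true
    in_c = (c >= cmin_range[0]) & (c <= cmin_range[1])
    in_a = (a >= auc_range[0]) & (a <= auc_range[1])
    return AttainmentSummary(
        n=len(cohort),
        pct_cmin_in_range=100.0 * float(in_c.mean()),
        pct_auc_in_range=100.0 * float(in_a.mean()),
        strategy=strategy)


def adjust_dose_proportional(
    current_dose,
    observed_value,
    target_value: float,
    allowed_doses: Sequence[float] = ALLOWED_DOSES,
):
    """Proportional-rule dose adjustment onto the allowed dose grid.

    ideal = current * target / observed; the nearest allowed dose is
    returned, exact midpoints breaking toward the lower dose.
    """
    allowed = np.sort(np.asarray(allowed_doses, float))
    obs = np.asarray(observed_value, float)
    if np.any(obs <= 0):
        raise ValueError("observed_value must be positive")
    ideal = np.asarray(current_dose, float) * target_value / obs
    dist = np.abs(allowed[None, :] - np.atleast_1d(ideal)[:, None])
    choice = allowed[np.argmin(dist, axis=1)]   # first minimum = lower dose
    if np.ndim(observed_value) == 0 and np.ndim(current_dose) == 0:
        return float(choice[0])
    return choice


def _rescale(cohort: VirtualCohort, new_dose: np.ndarray) -> VirtualCohort:
    """Recompute true exposures after re-dosing (dose-proportional model)."""
    ratio = new_dose / cohort.dose
    return VirtualCohort(
        bmi=cohort.bmi, cl=cohort.cl, v=cohort.v,
        half_life=cohort.half_life, dose=new_dose,
        ipred_true_cmin=cohort.ipred_true_cmin * ratio,
        auc_true=cohort.auc_true * ratio,
        cmin_ruv=cohort.cmin_ruv * ratio, tau=cohort.tau)


def apply_strategy(
    cohort: VirtualCohort,
    strategy: TdmStrategy,
    pop: Optional[PopulationModel] = None,
    seed: Optional[int] = None,
) -> tuple[VirtualCohort, AttainmentSummary]:
    """One TDM adjustment cycle under the given strategy.

    proportional_cmin applies the rule to the noisy trough directly;
    mipd_cmin / mipd_auc first compute a MAP-Bayes individual estimate
    from the single noisy trough, then apply the rule to the
    Bayes-predicted metric.  Attainment is summarized on the recomputed
    true exposures at the adjusted doses.
    """
    pop = pop or PopulationModel()
    if strategy.kind == "none":
        return cohort, attainment(cohort, strategy="none")
    if strategy.kind == "proportional_cmin":
        observed = cohort.cmin_ruv
    elif strategy.kind in ("mipd_cmin", "mipd_auc"):
        eta = map_from_single_trough(pop, cohort.bmi, cohort.dose,
                                     cohort.tau, cohort.cmin_ruv)
        cl_hat = pop.tvcl * np.exp(eta[:, 0])
        v_hat = (pop.tvv * (cohort.bmi / pop.bmi_ref) ** pop.bmi_power
                 * np.exp(eta[:, 1]))
        if strategy.kind == "mipd_cmin":
            observed = cmin_ss_batch(cohort.dose, cohort.tau, cl_hat, v_hat,
                                     pop.ka, pop.f_oral)
        else:
            observed = pop.f_oral * cohort.dose / cl_hat
    else:
        raise ValueError(f"unknown strategy kind {strategy.kind!r}")
    new_dose = adjust_dose_proportional(
        cohort.dose, observed, strategy.target_value, strategy.allowed_doses)
    if strategy.adjust_only_outside_range:
        lo, hi = strategy.target_range
        outside = (observed < lo) | (observed > hi)
        new_dose = np.where(outside, new_dose, cohort.dose)
    adjusted = _rescale(cohort, new_dose)
    return adjusted, attainment(adjusted, strategy=strategy.kind)
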