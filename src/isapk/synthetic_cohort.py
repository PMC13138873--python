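"""Synthetic TDM cohort generator.

Emulates the statistical structure of a real-life isavuconazole TDM
cohort: ~41 subjects with a median of 4 (range 1-11) concentration
samples each, once-daily doses of 100-400 mg, an IV lead-in followed by
oral dosing such that ~80% of samples fall under oral administration,
mostly trough sampling, BMI spanning 12-40 kg/m2, and concentrations
generated from the population model with mixed
proportional + additive residual error.  The generator returns both the
subject records and a hidden truth table (etas, true CL/V and true
steady-state exposures) for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    INTRAVENOUS,
    ORAL,
    CovariateRecord,
    DoseEvent,
    Observation,
    OutcomeLabels,
    PopulationModel,
    SubjectRecord,
)
from .pk_core import cmin_ss, concentration, individual_parameters

#: samples-per-subject pmf over 1..11 (median 4, range 1-11)
SAMPLES_PMF = np.array(
    [0.10, 0.12, 0.15, 0.18, 0.13, 0.10, 0.08, 0.06, 0.04, 0.02, 0.02])

DOSE_LEVELS = (100.0, 200.0, 300.0, 400.0)
DOSE_PROBS = (0.10, 0.60, 0.15, 0.15)


@dataclass
class OutcomeModel:
    """Logistic efficacy model on log true trough; toxicity is flat (null)."""

    intercept: float = -2.14
    slope: float = 1.5
    toxicity_rate: float = 0.28
    discontinuation_given_toxicity: float = 0.24


@dataclass
class CohortSpec:
    n_subjects: int = 41
    dose_levels: tuple = DOSE_LEVELS
    dose_probs: tuple = DOSE_PROBS
    frac_oral_samples: float = 0.8
    trough_fraction: float = 0.8
    bmi_range: tuple = (12.0, 40.0)
    true_model: PopulationModel = field(default_factory=PopulationModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    samples_per_subject: Optional[int] = None   # None -> SAMPLES_PMF draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.frac_oral_samples <= 1:
            raise ValueError("frac_oral_samples must be in [0, 1]")
        if not self.dose_levels:
            raise ValueError("dose_levels must not be empty")
        if len(self.dose_levels) != len(self.dose_probs):
            raise ValueError("dose_levels / dose_probs length mismatch")


def egfr_ckd_epi(creatinine: float, age: float, sex: str) -> float:
    """2009 CKD-EPI estimated GFR (mL/min/1.73 m2), race term omitted.

    ``creatinine`` in umol/L (converted to mg/dL by /88.4); sex-specific
    kappa and alpha; published table coefficients (144 female, 141 male).
    """
    if not creatinine > 0:
        raise ValueError("creatinine must be positive")
    scr = creatinine / 88.4
    if sex == "female":
        kappa, alpha, coef = 0.7, -0.329, 144.0
    elif sex == "male":
        kappa, alpha, coef = 0.9, -0.411, 141.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    r = scr / kappa
    return coef * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 \
        * 0.993 ** age


def _draw_clipped(rng, draw, lo, hi, size=None):
    out = draw(size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = draw(int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate subject records plus the hidden truth table.

    Each subject receives a fixed once-daily dose with an IV (1-h
    infusion) lead-in covering ~(1 - frac_oral_samples) of the treatment
    days, then oral dosing.  Sampling days are uniform over the
    treatment course; a ``trough_fraction`` of samples sit 23.75 h after
    a dose (15 min before the next), the rest 1-8 h post-dose.
    """
    rng = np.random.default_rng(spec.seed)
    pop = spec.true_model
    n = spec.n_subjects

    # log-normal around the published median, wide enough that a cohort of
    # ~41 plausibly spans the published 12-40 kg/m2 range
    bmi = _draw_clipped(
        rng, lambda s: rng.lognormal(math.log(24.0), 0.30, s),
        spec.bmi_range[0], spec.bmi_range[1], n)
    height = _draw_clipped(rng, lambda s: rng.normal(171.0, 9.0, s),
                           150.0, 188.0, n)
    age = _draw_clipped(rng, lambda s: rng.normal(61.0, 14.0, s),
                        20.0, 83.0, n)
    male = rng.random(n) < 0.56
    crea = _draw_clipped(
        rng, lambda s: rng.lognormal(math.log(86.0), 0.55, s), 16.0, 398.0, n)
    tbil = _draw_clipped(
        rng, lambda s: rng.lognormal(math.log(6.0), 0.9, s), 2.0, 98.0, n)
    albumin = _draw_clipped(rng, lambda s: rng.normal(33.0, 6.0, s),
                            14.0, 46.0, n)

    eta_cl = rng.normal(0.0, pop.omega_cl, n) if pop.omega_cl > 0 \
        else np.zeros(n)
    eta_v = rng.normal(0.0, pop.omega_v, n) if pop.omega_v > 0 \
        else np.zeros(n)
    doses_daily = rng.choice(spec.dose_levels, size=n, p=spec.dose_probs)

    subjects: list[SubjectRecord] = []
    truth_rows = []
    for i in range(n):
        ind = individual_parameters(pop, bmi[i], eta_cl[i], eta_v[i])
        n_days = int(rng.integers(28, 56))
        iv_days = int(round((1.0 - spec.frac_oral_samples) * n_days))
        dose_events = []
        for d in range(n_days):
            if d < iv_days:
                dose_events.append(DoseEvent(
                    time=24.0 * d, amount=doses_daily[i],
                    route=INTRAVENOUS, infusion_duration=1.0))
            else:
                dose_events.append(DoseEvent(
                    time=24.0 * d, amount=doses_daily[i], route=ORAL))

        if spec.samples_per_subject is not None:
            k = spec.samples_per_subject
        else:
            k = int(rng.choice(np.arange(1, 12), p=SAMPLES_PMF))
        k = min(k, n_days - 3)
        days = rng.choice(np.arange(2, n_days), size=k, replace=False)
        obs = []
        for day in sorted(days):
            if rng.random() < spec.trough_fraction:
                tad = 23.75
            else:
                tad = float(rng.uniform(1.0, 8.0))
            t = 24.0 * day + tad
            f = concentration(t, dose_events, ind, pop.f_oral)
            y = -1.0
            while y <= 0:
                y = f * (1.0 + rng.normal(0.0, pop.sigma_prop)) \
                    + rng.normal(0.0, pop.sigma_add)
            obs.append(Observation(time=t, value=float(y)))

        sex = "male" if male[i] else "female"
        weight = bmi[i] * (height[i] / 100.0) ** 2
        baseline = CovariateRecord(
            time=0.0, body_weight=round(weight, 1), height=height[i],
            age=age[i], sex=sex, bmi=bmi[i], creatinine=crea[i],
            egfr=egfr_ckd_epi(crea[i], age[i], sex),
            total_bilirubin=tbil[i], albumin=albumin[i],
            alt=float(rng.lognormal(math.log(30.0), 0.6)),
            ast=float(rng.lognormal(math.log(28.0), 0.6)),
            alp=float(rng.lognormal(math.log(80.0), 0.5)),
            ggt=float(rng.lognormal(math.log(50.0), 0.7)))

        sid = f"S{i + 1:03d}"
        subjects.append(SubjectRecord(
            subject_id=sid, centre=int(rng.integers(1, 3)),
            doses=dose_events, observations=obs, covariates=[baseline]))
        truth_rows.append((
            sid, bmi[i], doses_daily[i], eta_cl[i], eta_v[i], ind.cl, ind.v,
            cmin_ss(doses_daily[i], 24.0, ind, pop.f_oral),
            pop.f_oral * doses_daily[i] / ind.cl,
            24.0 * n_days))
    truth = pd.DataFrame(truth_rows, columns=[
        "subject_id", "bmi", "daily_dose", "eta_cl", "eta_v", "cl", "v",
        "cmin_ss_true", "auc_true", "end_of_treatment"])
    return subjects, truth


def generate_outcomes(
    truth_table: pd.DataFrame,
    outcome_model: Optional[OutcomeModel] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw outcome labels from the truth table's true exposures.

    success ~ Bernoulli(logistic(a + b ln C_min_true)); hepatotoxicity is
    exposure-independent by default (no association in the null model),
    with discontinuation only among toxic subjects.
    """
    om = outcome_model or OutcomeModel()
    rng = np.random.default_rng(seed)
    lin = om.intercept + om.slope * np.log(
        truth_table["cmin_ss_true"].to_numpy())
    p_success = 1.0 / (1.0 + np.exp(-lin))
    success = (rng.random(len(truth_table)) < p_success).astype(int)
    tox = (rng.random(len(truth_table)) < om.toxicity_rate).astype(int)
    disc = ((rng.random(len(truth_table))
             < om.discontinuation_given_toxicity) & (tox == 1)).astype(int)
    return pd.DataFrame({
        "subject_id": truth_table["subject_id"],
        "success": success,
        "hepatotoxicity": tox,
        "discontinuation": disc,
    })


def attach_outcomes(subjects: list[SubjectRecord], outcomes: pd.DataFrame,
                    truth_table: pd.DataFrame) -> None:
    """Attach generated outcome labels (with evaluation dates) in place."""
    end = dict(zip(truth_table["subject_id"], truth_table["end_of_treatment"]))
    by_id = outcomes.set_index("subject_id")
    for s in subjects:
        if s.subject_id in by_id.index:
            row = by_id.loc[s.subject_id]
            s.outcome_labels = OutcomeLabels(
                success=int(row["success"]),
                hepatotoxicity=int(row["hepatotoxicity"]),
                discontinuation=int(row["discontinuation"]),
                evaluation_time=float(end[s.subject_id]))
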