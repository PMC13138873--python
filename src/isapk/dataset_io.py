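"""Reading, writing and validation of NONMEM-dialect longitudinal datasets.

The on-disk dialect is a flat comma-separated table with one row per
event, ``.`` for missing values, and the usual columns:

========  =====================================================
ID        subject identifier
TIME      hours since the subject's first record
AMT       dose amount (mg), 0/missing on observation rows
RATE      infusion rate (mg/h); > 0 marks a zero-order infusion
EVID      1 = dose event, 0 = observation
CMT       1 = oral depot, 2 = central (IV dose / observation)
DV        measured concentration (mg/L)
MDV       1 = concentration missing / ignored
========  =====================================================

plus optional covariate columns (WT, HT, AGE, SEX, BMI, CREA, EGFR,
TBIL, ALB, ALT, AST, ALP, GGT) and CENTRE.  SEX is coded 1 = male,
0 = female.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    INTRAVENOUS,
    ORAL,
    CovariateRecord,
    DoseEvent,
    Observation,
    SubjectRecord,
)

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV"]

#: canonical covariate name -> dataset column
COVARIATE_COLUMNS = {
    "body_weight": "WT",
    "height": "HT",
    "age": "AGE",
    "sex": "SEX",
    "bmi": "BMI",
    "creatinine": "CREA",
    "egfr": "EGFR",
    "total_bilirubin": "TBIL",
    "albumin": "ALB",
    "alt": "ALT",
    "ast": "AST",
    "alp": "ALP",
    "ggt": "GGT",
}


class DatasetFormatError(ValueError):
    """Raised when a dataset violates the dialect contract."""


def _resolve_columns(dialect_config: Optional[dict]) -> dict:
    """Merge a dialect config's column renames onto the defaults."""
    columns = {c: c for c in MANDATORY_COLUMNS + ["CMT", "CENTRE"]}
    columns.update({v: v for v in COVARIATE_COLUMNS.values()})
    if dialect_config and "columns" in dialect_config:
        columns.update(dialect_config["columns"])
    return columns


def read_dataset(
    path: str | Path,
    dialect_config: Optional[dict] = None,
) -> list[SubjectRecord]:
    """Parse a NONMEM-dialect CSV into one :class:`SubjectRecord` per ID."""
    cols = _resolve_columns(dialect_config)
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    for canonical in MANDATORY_COLUMNS:
        if cols[canonical] not in df.columns:
            raise DatasetFormatError(
                f"missing mandatory column {cols[canonical]!r}")

    subjects: list[SubjectRecord] = []
    for sid, grp in df.groupby(cols["ID"], sort=False):
        times = grp[cols["TIME"]].to_numpy(float)
        if np.any(np.diff(times) < 0):
            raise DatasetFormatError(
                f"non-monotone TIME within subject {sid}")
        doses, observations, covrecs = [], [], []
        centre = 1
        if cols["CENTRE"] in grp.columns:
            c = grp[cols["CENTRE"]].dropna()
            if len(c):
                centre = int(c.iloc[0])
        for _, row in grp.iterrows():
            t = float(row[cols["TIME"]])
            evid = int(row[cols["EVID"]])
            if evid == 1:
                amt = float(row[cols["AMT"]])
                rate = row[cols["RATE"]]
                rate = 0.0 if pd.isna(rate) else float(rate)
                cmt = int(row.get(cols["CMT"], 1) if not pd.isna(
                    row.get(cols["CMT"], 1)) else 1)
                if rate > 0:
                    doses.append(DoseEvent(time=t, amount=amt,
                                           route=INTRAVENOUS,
                                           infusion_duration=amt / rate))
                elif cmt == 2:
                    doses.append(DoseEvent(time=t, amount=amt,
                                           route=INTRAVENOUS))
                else:
                    doses.append(DoseEvent(time=t, amount=amt, route=ORAL))
            else:
                dv = row[cols["DV"]]
                mdv = int(row[cols["MDV"]])
                if mdv == 1 and not pd.isna(dv) and float(dv) > 0:
                    warnings.warn(
                        f"subject {sid}: DV > 0 on an MDV=1 row at t={t}")
                value = float(dv) if not pd.isna(dv) else float("nan")
                observations.append(
                    Observation(time=t, value=value, is_missing=mdv == 1))
            kwargs = {}
            for canonical, col in COVARIATE_COLUMNS.items():
                col = cols[col]
                if col in grp.columns and not pd.isna(row[col]):
                    val = row[col]
                    if canonical == "sex":
                        kwargs["sex"] = "male" if int(val) == 1 else "female"
                    else:
                        kwargs[canonical] = float(val)
            if kwargs:
                covrecs.append(CovariateRecord(time=t, **kwargs))
        subjects.append(SubjectRecord(
            subject_id=str(sid), centre=centre, doses=doses,
            observations=observations, covariates=covrecs))
    return subjects


def write_dataset(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    """Inverse of :func:`read_dataset`; numeric fields round-trip exactly."""
    rows = []
    for s in subjects:
        events = ([("dose", d.time, d) for d in s.doses]
                  + [("obs", o.time, o) for o in s.observations])
        events.sort(key=lambda e: (e[1], e[0] == "dose"))
        cov_by_time = {c.time: c for c in s.covariates}
        for kind, t, ev in events:
            row = {"ID": s.subject_id, "TIME": t, "CENTRE": s.centre}
            if kind == "dose":
                row.update(AMT=ev.amount, EVID=1, DV=np.nan, MDV=1,
                           CMT=1 if ev.route == ORAL else 2,
                           RATE=(ev.amount / ev.infusion_duration
                                 if ev.infusion_duration > 0 else 0.0))
            else:
                row.update(AMT=0.0, RATE=0.0, EVID=0, CMT=2,
                           DV=np.nan if ev.is_missing else ev.value,
                           MDV=int(ev.is_missing))
            c = cov_by_time.get(t)
            if c is not None:
                for canonical, col in COVARIATE_COLUMNS.items():
                    v = getattr(c, canonical)
                    if v is None:
                        continue
                    row[col] = (1 if v == "male" else 0) \
                        if canonical == "sex" else v
            rows.append(row)
    df = pd.DataFrame(rows)
    ordered = ["ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "MDV",
               "CENTRE"] + [c for c in COVARIATE_COLUMNS.values()
                            if c in df.columns]
    df = df.reindex(columns=ordered)
    # shortest-round-trip float formatting so numeric fields survive
    # write -> read bit-exactly (pandas' default truncates)
    int_cols = {"ID", "EVID", "CMT", "MDV", "CENTRE", "SEX"}

    def fmt(col, v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "."
        if col in int_cols:
            return str(int(v)) if not isinstance(v, str) else v
        return repr(float(v))

    out = df.apply(lambda s: [fmt(s.name, v) for v in s])
    out.to_csv(path, index=False)


def interpolate_covariate(
    records: Sequence[CovariateRecord],
    name: str,
    query_time: float,
) -> Optional[float]:
    """Linearly interpolate a covariate between quantified values.

    Outside the quantified window the nearest value is carried.  Returns
    ``None`` when the covariate was never quantified (caller decides how
    to handle exclusion).
    """
    pts = [(r.time, getattr(r, name)) for r in records
           if getattr(r, name) is not None]
    if not pts:
        return None
    pts.sort()
    times = np.array([p[0] for p in pts], float)
    values = np.array([p[1] for p in pts], float)
    return float(np.interp(query_time, times, values))


def dichotomize_lab(value: float, upper_limit_normal: float) -> int:
    """1 iff the lab value exceeds twice the upper limit of normal."""
    if not upper_limit_normal > 0:
        raise ValueError("upper_limit_normal must be positive")
    return int(value > 2.0 * upper_limit_normal)


def build_imputed_trough_subject(
    subject_id: str,
    centre: int,
    daily_dose: float,
    trough_values: Sequence[float],
    n_lead_in_days: int = 14,
) -> SubjectRecord:
    """Represent a record with unknown exact times (centre-3 style).

    Dose times are imputed to a nominal once-daily schedule and each
    concentration is placed 24 h after a dose (a trough, as per routine
    triazole TDM practice); all events are flagged ``imputed``.
    """
    n_days = n_lead_in_days + len(trough_values)
    doses = [DoseEvent(time=24.0 * d, amount=daily_dose, imputed=True)
             for d in range(n_days)]
    obs = [Observation(time=24.0 * (n_lead_in_days + i), value=v,
                       imputed=True)
           for i, v in enumerate(trough_values)]
    return SubjectRecord(subject_id=subject_id, centre=centre,
                         doses=doses, observations=obs)
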