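"""Exploratory exposure-response and exposure-toxicity logistic regressions.

Outcome (treatment success, hepatotoxicity or discontinuation) is
regressed on log-transformed exposure (C_min or AUC) by maximum
likelihood; the p-value is a likelihood-ratio test against the
intercept-only model.  Sensitivity refits drop configurable record
subsets (a centre, explicit subject ids, or exposure-quantile extremes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ExposureOutcomeRecord:
    subject_id: str
    centre: int
    cmin: float
    auc: float
    success: Optional[int] = None
    hepatotoxicity: Optional[int] = None
    discontinuation: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.cmin > 0 and self.auc > 0):
            raise ValueError("exposures must be positive")


@dataclass
class LogisticResult:
    intercept: float
    slope: float
    p_value: float
    n: int
    exposure: str
    outcome: str
    separated: bool = False
    label: str = "full"

    def probability(self, exposure_value) -> np.ndarray:
        """Fitted success probability at the given exposure (same units)."""
        lin = self.intercept + self.slope * np.log(
            np.asarray(exposure_value, float))
        return 1.0 / (1.0 + np.exp(-lin))


def _records_frame(records: Sequence[ExposureOutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def fit_exposure_outcome(
    records: Sequence[ExposureOutcomeRecord],
    exposure: str = "cmin",
    outcome: str = "success",
    label: str = "full",
) -> LogisticResult:
    """ML logistic fit of an outcome on ln(exposure) with an LR p-value."""
    if exposure not in ("cmin", "auc"):
        raise ValueError("exposure must be 'cmin' or 'auc'")
    df = _records_frame(records)
    df = df.dropna(subset=[outcome])
    y = df[outcome].astype(float).to_numpy()
    if len(df) < 2 or y.min() == y.max():
        raise ValueError(
            f"outcome {outcome!r} shows no variation; logistic fit "
            "is undefined")
    x = np.log(df[exposure].to_numpy(float))
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            model = sm.Logit(y, X).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones_like(y)).fit(disp=0)
        separated = not np.all(np.isfinite(model.bse))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        # complete separation: report it; no p-value fabricated
        return LogisticResult(intercept=float("nan"), slope=float("nan"),
                              p_value=float("nan"), n=len(df),
                              exposure=exposure, outcome=outcome,
                              separated=True, label=label)
    lr = 2.0 * (model.llf - null.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return LogisticResult(
        intercept=float(model.params[0]), slope=float(model.params[1]),
        p_value=p if not separated else float("nan"), n=len(df),
        exposure=exposure, outcome=outcome, separated=separated, label=label)


@dataclass
class DropRule:
    """A labelled record filter for sensitivity analysis.

    Exactly one of ``centre``, ``subject_ids`` or ``exposure_quantiles``
    is typically set; records matching the rule are dropped.
    """

    label: str
    centre: Optional[int] = None
    subject_ids: Optional[Sequence[str]] = None
    exposure_quantiles: Optional[tuple] = None   # (low_q, high_q) on cmin+auc

    def apply(self, records: Sequence[ExposureOutcomeRecord]
              ) -> list[ExposureOutcomeRecord]:
        kept = list(records)
        if self.centre is not None:
            kept = [r for r in kept if r.centre != self.centre]
        if self.subject_ids is not None:
            drop = set(self.subject_ids)
            kept = [r for r in kept if r.subject_id not in drop]
        if self.exposure_quantiles is not None:
            lo_q, hi_q = self.exposure_quantiles
            for attr in ("cmin", "auc"):
                vals = np.array([getattr(r, attr) for r in records])
                lo, hi = np.quantile(vals, [lo_q, hi_q])
                kept = [r for r in kept
                        if lo <= getattr(r, attr) <= hi]
        return kept


def sensitivity_refit(
    records: Sequence[ExposureOutcomeRecord],
    drop_rules: Sequence[DropRule],
    exposure: str = "cmin",
    outcome: str = "success",
) -> list[LogisticResult]:
    """One labelled refit per drop rule."""
    results = []
    for rule in drop_rules:
        kept = rule.apply(records)
        results.append(fit_exposure_outcome(
            kept, exposure=exposure, outcome=outcome, label=rule.label))
    return results


def results_table(results: Sequence[LogisticResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
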