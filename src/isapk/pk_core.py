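"""One-compartment PK model with first-order absorption and linear elimination.

Closed-form concentration profiles under superposition of oral doses,
IV boluses and zero-order infusions, plus steady-state exposure metrics
(trough, AUC over the dosing interval, Tmax, half-life).

Everything here is a deterministic pure function.  The ``*_batch``
helpers evaluate the same closed forms for whole cohorts at once and are
the computational backbone of the estimation and simulation modules.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .datatypes import (
    ORAL,
    DoseEvent,
    IndividualParameters,
    PopulationModel,
)

_KA_KE_RTOL = 1e-9


def individual_parameters(
    pop: PopulationModel,
    bmi: float,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """Apply the final-model covariate and random-effect equations.

    CL_i = TVCL * exp(eta_cl)
    V_i  = TVV * (BMI_i / bmi_ref)**bmi_power * exp(eta_v)
    """
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    cl = pop.tvcl * math.exp(eta_cl)
    v = pop.tvv * (bmi / pop.bmi_ref) ** pop.bmi_power * math.exp(eta_v)
    return IndividualParameters(cl=cl, v=v, ka=pop.ka,
                                eta_cl=eta_cl, eta_v=eta_v)


def _check_ka_ke(ka: float, ke: float) -> None:
    if abs(ka - ke) <= _KA_KE_RTOL * max(ka, ke):
        raise ValueError("degenerate model: ka == ke")


def concentration(
    t: float | np.ndarray,
    doses: Sequence[DoseEvent],
    ind: IndividualParameters,
    f_oral: float = 1.0,
) -> float | np.ndarray:
    """Concentration at time(s) ``t`` by superposition over the dose history.

    Oral dose:    F*D*ka / (V*(ka-ke)) * (exp(-ke*dt) - exp(-ka*dt))
    IV bolus:     (D/V) * exp(-ke*dt)
    IV infusion:  zero-order input solution (during and after the infusion)

    Doses not yet given (dt < 0) contribute nothing.
    """
    ke = ind.cl / ind.v
    _check_ka_ke(ind.ka, ke)
    t_arr = np.asarray(t, dtype=float)
    c = np.zeros_like(t_arr)
    for d in doses:
        dt = t_arr - d.time
        mask = dt > 0
        if not np.any(mask):
            continue
        dtm = np.where(mask, dt, 0.0)
        if d.route == ORAL:
            coef = f_oral * d.amount * ind.ka / (ind.v * (ind.ka - ke))
            contrib = coef * (np.exp(-ke * dtm) - np.exp(-ind.ka * dtm))
        elif d.infusion_duration > 0:
            rate = d.amount / d.infusion_duration
            during = rate / ind.cl * (1.0 - np.exp(-ke * dtm))
            after = (rate / ind.cl
                     * (1.0 - np.exp(-ke * d.infusion_duration))
                     * np.exp(-ke * (dtm - d.infusion_duration)))
            contrib = np.where(dtm <= d.infusion_duration, during, after)
        else:
            contrib = d.amount / ind.v * np.exp(-ke * dtm)
        c += np.where(mask, contrib, 0.0)
    if np.ndim(t) == 0:
        return float(c)
    return c


def cmin_ss(
    dose: float,
    tau: float,
    ind: IndividualParameters,
    f_oral: float = 1.0,
) -> float:
    """Steady-state trough under repeated oral dosing every ``tau`` hours."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    ke = ind.cl / ind.v
    _check_ka_ke(ind.ka, ke)
    coef = f_oral * dose * ind.ka / (ind.v * (ind.ka - ke))
    acc_ke = math.exp(-ke * tau) / (1.0 - math.exp(-ke * tau))
    acc_ka = math.exp(-ind.ka * tau) / (1.0 - math.exp(-ind.ka * tau))
    return coef * (acc_ke - acc_ka)


def auc_ss(dose: float, ind: IndividualParameters, f_oral: float = 1.0) -> float:
    """Steady-state AUC over one dosing interval: F*dose/CL."""
    return f_oral * dose / ind.cl


def tmax(ind: IndividualParameters) -> float:
    """Time to peak after a single oral dose: ln(ka/ke)/(ka-ke)."""
    ke = ind.cl / ind.v
    if ind.ka <= ke:
        raise ValueError("tmax requires ka > ke")
    return math.log(ind.ka / ke) / (ind.ka - ke)


def half_life(ind: IndividualParameters) -> float:
    """Terminal elimination half-life: ln(2)*V/CL."""
    return math.log(2.0) * ind.v / ind.cl


def exposure_metrics(
    dose: float,
    tau: float,
    ind: IndividualParameters,
    f_oral: float = 1.0,
):
    from .datatypes import ExposureMetrics

    return ExposureMetrics(
        cmin_ss=cmin_ss(dose, tau, ind, f_oral),
        auc_tau=auc_ss(dose, ind, f_oral),
        tmax=tmax(ind),
        half_life=half_life(ind),
    )


# ---------------------------------------------------------------------------
# Vectorized cohort-level evaluation
# ---------------------------------------------------------------------------

def concentration_batch(
    t_obs: np.ndarray,
    dose_time: np.ndarray,
    dose_amt: np.ndarray,
    dose_oral: np.ndarray,
    dose_dur: np.ndarray,
    cl: np.ndarray,
    v: np.ndarray,
    ka: float,
    f_oral: float = 1.0,
) -> np.ndarray:
    """Concentrations for many subjects at once.

    Shapes: ``t_obs`` (n, O); dose arrays (n, D); ``cl``/``v`` (n,).
    Padding rows carry ``dose_amt == 0`` (doses) or any time (observations;
    callers mask the output).  Returns an (n, O) array.
    """
    cl = np.asarray(cl, float)[:, None, None]
    v = np.asarray(v, float)[:, None, None]
    ke = cl / v
    dt = t_obs[:, None, :] - dose_time[:, :, None]          # (n, D, O)
    active = (dt > 0) & (dose_amt[:, :, None] > 0)
    dtm = np.where(active, dt, 0.0)

    amt = dose_amt[:, :, None]
    oral = dose_oral[:, :, None].astype(bool)
    dur = dose_dur[:, :, None]

    exp_ke = np.exp(-ke * dtm)
    oral_c = f_oral * amt * ka / (v * (ka - ke)) * (exp_ke - np.exp(-ka * dtm))

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dur > 0, amt / np.where(dur > 0, dur, 1.0), 0.0)
        during = rate / cl * (1.0 - exp_ke)
        after = (rate / cl * (1.0 - np.exp(-ke * dur))
                 * np.exp(-ke * np.maximum(dtm - dur, 0.0)))
        inf_c = np.where(dtm <= dur, during, after)
    bolus_c = amt / v * exp_ke
    iv_c = np.where(dur > 0, inf_c, bolus_c)

    contrib = np.where(oral, oral_c, iv_c)
    return np.sum(np.where(active, contrib, 0.0), axis=1)


def concentration_blocks(
    t_obs: np.ndarray,
    blk_t0: np.ndarray,
    blk_n: np.ndarray,
    blk_delta: np.ndarray,
    blk_amt: np.ndarray,
    blk_oral: np.ndarray,
    blk_dur: np.ndarray,
    cl: np.ndarray,
    v: np.ndarray,
    ka: float,
    f_oral: float = 1.0,
) -> np.ndarray:
    """Concentrations via geometric-series sums over uniform dosing blocks.

    A block is a run of doses with equal amount, route and infusion
    duration given at a fixed interval ``blk_delta`` starting at
    ``blk_t0`` (``blk_n`` doses).  Summing the per-dose exponentials in
    closed form makes the cost independent of the number of doses, which
    matters for long once-daily histories.  Shapes: ``t_obs`` (n, O);
    block arrays (n, B); returns (n, O).  Padding blocks have
    ``blk_n == 0``.  Exactly equivalent to per-dose superposition.
    """
    cl = np.asarray(cl, float)[:, None, None]
    v = np.asarray(v, float)[:, None, None]
    ke = cl / v

    t = t_obs[:, None, :]                      # (n, 1, O)
    t0 = blk_t0[:, :, None]                    # (n, B, 1)
    delta = np.maximum(blk_delta[:, :, None], 1e-9)
    m = blk_n[:, :, None]
    amt = blk_amt[:, :, None]
    oral = blk_oral[:, :, None].astype(bool)
    dur = blk_dur[:, :, None]

    # number of doses already given (strictly before t)
    j = np.floor((t - t0 - 1e-9) / delta) + 1.0
    j = np.clip(j, 0.0, m)
    given = (j > 0) & (amt > 0)
    dt_last = np.where(given, t - t0 - (j - 1.0) * delta, 0.0)

    def geo_sum(rate_const):
        # sum_{i=0..j-1} exp(-rate*(dt_last + i*delta))
        rho = np.exp(-rate_const * delta)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(np.abs(1.0 - rho) > 1e-12,
                         (1.0 - rho ** j) / (1.0 - rho), j)
        return np.exp(-rate_const * dt_last) * s

    s_ke = geo_sum(ke)
    s_ka = geo_sum(np.broadcast_to(np.asarray(ka, float), ke.shape))

    oral_c = f_oral * amt * ka / (v * (ka - ke)) * (s_ke - s_ka)

    # IV: bolus when dur == 0, else zero-order infusion
    bolus_c = amt / v * s_ke
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dur > 0, amt / np.where(dur > 0, dur, 1.0), 0.0)
        during = (dt_last < dur) & given
        # completed-infusion sum excludes an ongoing last dose
        s_done = np.where(during, s_ke - np.exp(-ke * dt_last), s_ke)
        after_c = rate / cl * (np.exp(ke * dur) - 1.0) * s_done
        inf_c = after_c + np.where(
            during, rate / cl * (1.0 - np.exp(-ke * dt_last)), 0.0)
    iv_c = np.where(dur > 0, inf_c, bolus_c)

    contrib = np.where(oral, oral_c, iv_c)
    return np.sum(np.where(given, contrib, 0.0), axis=1)


def cmin_ss_batch(
    dose: np.ndarray | float,
    tau: float,
    cl: np.ndarray,
    v: np.ndarray,
    ka: float,
    f_oral: float = 1.0,
) -> np.ndarray:
    """Vectorized steady-state trough (oral once-per-tau dosing)."""
    cl = np.asarray(cl, float)
    v = np.asarray(v, float)
    ke = cl / v
    coef = f_oral * np.asarray(dose, float) * ka / (v * (ka - ke))
    acc_ke = np.exp(-ke * tau) / (1.0 - np.exp(-ke * tau))
    acc_ka = math.exp(-ka * tau) / (1.0 - math.exp(-ka * tau))
    return coef * (acc_ke - acc_ka)
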