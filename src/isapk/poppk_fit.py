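"""Nonlinear mixed-effects estimation and model-selection machinery.

The marginal likelihood integrates the per-subject random effects
(eta_cl, eta_v) out of the Gaussian residual model

    y_ij = f_ij * (1 + eps_prop) + eps_add,
    Var(y_ij | eta) = f_ij^2 * sigma_prop^2 + sigma_add^2,

using a Laplace approximation at the per-subject posterior mode.  The
inner mode search is a damped Newton iteration run for all subjects
simultaneously on padded arrays, which keeps full population fits (and
bootstrap/stepwise loops built on them) fast enough for routine use.

Model comparison follows likelihood-ratio thresholds of 3.84 (forward,
p=0.05) and 6.63 (backward, p=0.01) on the objective function value
(OFV = -2 log marginal likelihood), an AIC-decrease-of-2 rule for
non-nested models, |CWRES| > 3 outlier flagging, a nonparametric
bootstrap, and eta-shrinkage reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ORAL, PopulationModel, SubjectRecord
def _dose_blocks(doses) -> list[tuple]:
    """Greedily merge a dose list into uniform (t0, n, delta, amt, oral, dur)
    blocks: runs of equal amount/route/duration at a constant interval."""
    blocks: list[list] = []
    for d in doses:
        oral = 1.0 if d.route == ORAL else 0.0
        if blocks:
            b = blocks[-1]
            same = (b[3] == d.amount and b[4] == oral
                    and b[5] == d.infusion_duration)
            gap = d.time - (b[0] + (b[1] - 1) * b[2])
            if same and gap > 0 and (b[1] == 1 or abs(gap - b[2]) < 1e-9):
                if b[1] == 1:
                    b[2] = gap
                b[1] += 1
                continue
        blocks.append([d.time, 1, 24.0, d.amount, oral, d.infusion_duration])
    return [tuple(b) for b in blocks]

LOG2PI = math.log(2.0 * math.pi)

# parameters that live on the log scale during optimization
_POSITIVE_PARAMS = ("tvcl", "tvv", "ka", "f_oral",
                    "omega_cl", "omega_v", "sigma_prop", "sigma_add")
DEFAULT_FIXED = frozenset({"ka", "f_oral"})


# ---------------------------------------------------------------------------
# Covariate effects
# ---------------------------------------------------------------------------

POWER = "power_on_normalized"
LINEAR = "linear_centered"
CATEGORICAL = "categorical_shift"


@dataclass
class CovariateEffect:
    """A covariate-parameter relation tested by the stepwise engine.

    forms:
      power_on_normalized : multiplier (x / ref) ** theta
      linear_centered     : multiplier 1 + theta * (x - ref), floored at 0.01
      categorical_shift   : multiplier exp(theta * x) for x in {0, 1}
    """

    parameter: str            # "cl" or "v"
    covariate: str            # canonical covariate name
    form: str = POWER
    theta: float = 0.0
    ref: float = 1.0
    fixed: bool = False

    def multiplier(self, x: np.ndarray) -> np.ndarray:
        if self.form == POWER:
            return (x / self.ref) ** self.theta
        if self.form == LINEAR:
            return np.maximum(1.0 + self.theta * (x - self.ref), 0.01)
        if self.form == CATEGORICAL:
            return np.exp(self.theta * x)
        raise ValueError(f"unknown covariate form {self.form!r}")


def subject_covariate(subject: SubjectRecord, name: str) -> Optional[float]:
    """Subject-level scalar covariate: median of quantified values."""
    vals = []
    for rec in subject.covariates:
        v = getattr(rec, name)
        if v is None:
            continue
        if name == "sex":
            v = 1.0 if v == "male" else 0.0
        vals.append(float(v))
    if not vals:
        return None
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# Batched design
# ---------------------------------------------------------------------------

class Design:
    """Padded array representation of a subject list for vectorized fits."""

    def __init__(self, subjects: Sequence[SubjectRecord],
                 covariate_names: Sequence[str] = ()):
        self.subjects = list(subjects)
        n = len(self.subjects)
        if n == 0:
            raise ValueError("no subjects")
        for s in self.subjects:
            if s.n_observed < 1:
                raise ValueError(
                    f"subject {s.subject_id} has no usable observation")
        max_obs = max(s.n_observed for s in self.subjects)
        all_blocks = [_dose_blocks(s.doses) for s in self.subjects]
        max_blk = max(max(len(b), 1) for b in all_blocks)
        self.t_obs = np.zeros((n, max_obs))
        self.y = np.ones((n, max_obs))
        self.obs_mask = np.zeros((n, max_obs), dtype=bool)
        self.blk_t0 = np.zeros((n, max_blk))
        self.blk_n = np.zeros((n, max_blk))
        self.blk_delta = np.full((n, max_blk), 24.0)
        self.blk_amt = np.zeros((n, max_blk))
        self.blk_oral = np.zeros((n, max_blk))
        self.blk_dur = np.zeros((n, max_blk))
        self.bmi = np.empty(n)
        self.cov = {}
        for i, s in enumerate(self.subjects):
            obs = [o for o in s.observations if not o.is_missing]
            self.t_obs[i, :len(obs)] = [o.time for o in obs]
            self.y[i, :len(obs)] = [o.value for o in obs]
            self.obs_mask[i, :len(obs)] = True
            for j, (t0, cnt, delta, amt, oral, dur) in enumerate(all_blocks[i]):
                self.blk_t0[i, j] = t0
                self.blk_n[i, j] = cnt
                self.blk_delta[i, j] = delta
                self.blk_amt[i, j] = amt
                self.blk_oral[i, j] = oral
                self.blk_dur[i, j] = dur
            bmi = subject_covariate(s, "bmi")
            self.bmi[i] = bmi if bmi is not None else np.nan
        for name in covariate_names:
            self.cov[name] = np.array(
                [v if (v := subject_covariate(s, name)) is not None
                 else np.nan for s in self.subjects])
        self.n = n
        self.n_obs_total = int(self.obs_mask.sum())

        # precomputed dose-time geometry (independent of CL/V), so repeated
        # likelihood evaluations only pay for the exponentials
        t = self.t_obs[:, None, :]                       # (n, 1, O)
        t0 = self.blk_t0[:, :, None]                     # (n, B, 1)
        delta = np.maximum(self.blk_delta[:, :, None], 1e-9)
        mdose = self.blk_n[:, :, None]
        j = np.clip(np.floor((t - t0 - 1e-9) / delta) + 1.0, 0.0, mdose)
        self._geo_j = j
        self._geo_given = (j > 0) & (self.blk_amt[:, :, None] > 0)
        self._geo_dtlast = np.where(self._geo_given,
                                    t - t0 - (j - 1.0) * delta, 0.0)
        self._geo_delta = delta
        self._geo_amt = self.blk_amt[:, :, None]
        self._geo_oral = self.blk_oral[:, :, None].astype(bool)
        self._geo_dur = self.blk_dur[:, :, None]
        self._geo_any_iv = bool(np.any(~self._geo_oral & self._geo_given))

    def covariate_values(self, name: str) -> np.ndarray:
        if name == "bmi":
            return self.bmi
        if name not in self.cov:
            self.cov[name] = np.array(
                [v if (v := subject_covariate(s, name)) is not None
                 else np.nan for s in self.subjects])
        return self.cov[name]

    def individual_cl_v(self, pop: PopulationModel, eta: np.ndarray):
        """(cl, v) arrays for eta of shape (..., n, 2)."""
        m_cl = np.ones(self.n)
        bmi = np.where(np.isnan(self.bmi), pop.bmi_ref, self.bmi)
        m_v = (bmi / pop.bmi_ref) ** pop.bmi_power
        for eff in pop.covariate_effects:
            x = self.covariate_values(eff.covariate)
            x = np.where(np.isnan(x), eff.ref, x)
            mult = eff.multiplier(x)
            if eff.parameter == "cl":
                m_cl = m_cl * mult
            else:
                m_v = m_v * mult
        cl = pop.tvcl * m_cl * np.exp(eta[..., 0])
        v = pop.tvv * m_v * np.exp(eta[..., 1])
        return cl, v

    def predictions(self, pop: PopulationModel, eta: np.ndarray) -> np.ndarray:
        """Model concentrations for eta of shape (..., n, 2) -> (..., n, O).

        Uses the precomputed dose geometry with geometric-series block
        sums; leading eta dimensions (e.g. finite-difference stencils)
        are evaluated in one broadcast pass.
        """
        cl, v = self.individual_cl_v(pop, eta)          # (..., n)
        ka = pop.ka
        ke = (cl / v)[..., None, None]                  # (..., n, 1, 1)
        j = self._geo_j
        dt_last = self._geo_dtlast
        delta = self._geo_delta

        rho_ke = np.exp(-ke * delta)
        s_ke = np.exp(-ke * dt_last) * np.where(
            np.abs(1.0 - rho_ke) > 1e-12,
            (1.0 - rho_ke ** j) / np.where(np.abs(1.0 - rho_ke) > 1e-12,
                                           1.0 - rho_ke, 1.0), j)
        rho_ka = np.exp(-ka * delta)
        s_ka = np.exp(-ka * dt_last) * np.where(
            np.abs(1.0 - rho_ka) > 1e-12,
            (1.0 - rho_ka ** j) / np.where(np.abs(1.0 - rho_ka) > 1e-12,
                                           1.0 - rho_ka, 1.0), j)

        amt = self._geo_amt
        oral_c = (pop.f_oral * amt * ka
                  / (v[..., None, None] * (ka - ke)) * (s_ke - s_ka))
        if self._geo_any_iv:
            dur = self._geo_dur
            with np.errstate(all="ignore"):
                rate = np.where(dur > 0, amt / np.where(dur > 0, dur, 1.0),
                                0.0)
                during = (dt_last < dur) & self._geo_given
                s_done = np.where(during, s_ke - np.exp(-ke * dt_last), s_ke)
                inf_c = rate / cl[..., None, None] * (
                    (np.exp(ke * dur) - 1.0) * s_done
                    + np.where(during, 1.0 - np.exp(-ke * dt_last), 0.0))
            bolus_c = amt / v[..., None, None] * s_ke
            iv_c = np.where(dur > 0, inf_c, bolus_c)
            contrib = np.where(self._geo_oral, oral_c, iv_c)
        else:
            contrib = np.where(self._geo_oral, oral_c, 0.0)
        return np.sum(np.where(self._geo_given, contrib, 0.0), axis=-2)


# ---------------------------------------------------------------------------
# Laplace marginal likelihood
# ---------------------------------------------------------------------------

def _joint_neg2ll(design: Design, pop: PopulationModel,
                  eta: np.ndarray) -> np.ndarray:
    """Per-subject -2 log [p(y|eta) p(eta)] up to the prior normalizer.

    Returns G(eta) = sum_j [ln(2 pi v_j) + r_j^2 / v_j] + eta' Omega^-1 eta
    over active dimensions (omega > 0); inactive etas must be zero.
    Accepts stacked etas of shape (..., n, 2) and returns (..., n).
    """
    with np.errstate(all="ignore"):
        f = design.predictions(pop, eta)
        var = (f * pop.sigma_prop) ** 2 + pop.sigma_add ** 2
        var = np.maximum(var, 1e-12)
        resid = np.where(design.obs_mask, (design.y - f) ** 2 / var
                         + np.log(2.0 * np.pi * var), 0.0)
        g = resid.sum(axis=-1)
        if pop.omega_cl > 0:
            g = g + eta[..., 0] ** 2 / pop.omega_cl ** 2
        if pop.omega_v > 0:
            g = g + eta[..., 1] ** 2 / pop.omega_v ** 2
    # divergent etas (overflowing exponentials) get a finite penalty so the
    # damped Newton iteration backtracks instead of propagating NaNs
    return np.where(np.isfinite(g), g, 1e10)


def _active_dims(pop: PopulationModel) -> list[int]:
    dims = []
    if pop.omega_cl > 0:
        dims.append(0)
    if pop.omega_v > 0:
        dims.append(1)
    return dims


def _stencil_offsets(d: int) -> np.ndarray:
    """Finite-difference stencil offsets (unit steps), centre first."""
    offs = [np.zeros(d)]
    for a in range(d):
        for sgn in (1, -1):
            e = np.zeros(d)
            e[a] = sgn
            offs.append(e)
    for a in range(d):
        for b in range(a + 1, d):
            for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                e = np.zeros(d)
                e[a], e[b] = sa, sb
                offs.append(e)
    return np.array(offs)                      # (K, d)


def _grad_hess(fun, eta: np.ndarray, dims: list[int], h: float = 1e-4):
    """Central finite-difference gradient and Hessian over active dims.

    ``fun`` maps (..., n, 2) -> (..., n); the whole stencil is evaluated
    in one broadcast call.  Returns (f0, g, H) with shapes (n,), (n, d)
    and (n, d, d).
    """
    n = eta.shape[0]
    d = len(dims)
    offs = _stencil_offsets(d)                 # (K, d)
    K = offs.shape[0]
    etas = np.broadcast_to(eta, (K, n, 2)).copy()
    for k, dim in enumerate(dims):
        etas[:, :, dim] += h * offs[:, None, k]
    vals = fun(etas)                           # (K, n)

    f0 = vals[0]
    g = np.zeros((n, d))
    H = np.zeros((n, d, d))
    idx = 1
    plus, minus = {}, {}
    for a in range(d):
        plus[a], minus[a] = vals[idx], vals[idx + 1]
        g[:, a] = (vals[idx] - vals[idx + 1]) / (2 * h)
        H[:, a, a] = (vals[idx] - 2 * f0 + vals[idx + 1]) / h ** 2
        idx += 2
    for a in range(d):
        for b in range(a + 1, d):
            Hab = (vals[idx] - vals[idx + 1] - vals[idx + 2]
                   + vals[idx + 3]) / (4 * h ** 2)
            H[:, a, b] = H[:, b, a] = Hab
            idx += 4
    return f0, g, H


def _posterior_modes(design: Design, pop: PopulationModel,
                     eta0: Optional[np.ndarray] = None,
                     max_iter: int = 40, tol: float = 1e-7):
    """Vectorized damped Newton search for all per-subject eta modes."""
    n = design.n
    dims = _active_dims(pop)
    eta = np.zeros((n, 2)) if eta0 is None else eta0.copy()
    for dim in (0, 1):
        if dim not in dims:
            eta[:, dim] = 0.0
    if not dims:
        return eta, _joint_neg2ll(design, pop, eta), None

    fun = lambda e: _joint_neg2ll(design, pop, e)
    d = len(dims)
    eta_cap = 12.0

    # the per-subject joint density can be multimodal with sparse data:
    # scan a coarse eta grid (plus any warm start) and begin Newton from
    # the per-subject best candidate
    candidates = [np.zeros((n, 2))]
    if eta0 is not None:
        candidates.append(eta.copy())
    # grid levels scale with each omega so wide-IIV models are covered
    levels = {}
    for dim in dims:
        om = pop.omega_cl if dim == 0 else pop.omega_v
        s = min(max(om, 0.1), 2.0)
        pts = [-2.0, -1.0, 0.0, 1.0, 2.0]
        if om > 0.45:   # wide-IIV posteriors are the multimodal ones
            pts = [-2.5, -1.75, -1.0, -0.5, 0.0, 0.5, 1.0, 1.75, 2.5]
        levels[dim] = [p * s for p in pts]
    if d == 1:
        combos = [(a,) for a in levels[dims[0]] if a != 0.0]
    else:
        combos = [(a, b) for a in levels[dims[0]] for b in levels[dims[1]]
                  if not (a == 0.0 and b == 0.0)]
    for combo in combos:
        e = np.zeros((n, 2))
        for k, dim in enumerate(dims):
            e[:, dim] = combo[k]
        candidates.append(e)
    cand = np.stack(candidates, axis=0)        # (C, n, 2)
    vals = fun(cand)
    pick = np.argmin(vals, axis=0)
    eta = cand[pick, np.arange(n), :]
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            f0, g, H = _grad_hess(fun, eta, dims)
            g = np.where(np.isfinite(g), g, 0.0)
            H = np.where(np.isfinite(H), H, 0.0)
            # ridge any non-PD subject Hessian toward the prior curvature
            diag_min = np.min(np.diagonal(H, axis1=1, axis2=2), axis=1)
            det = np.linalg.det(H) if d > 1 else H[:, 0, 0]
            bad = (diag_min <= 0) | (det <= 0) | ~np.isfinite(det)
            if np.any(bad):
                prior = np.zeros((d, d))
                for k, dim in enumerate(dims):
                    om = pop.omega_cl if dim == 0 else pop.omega_v
                    prior[k, k] = 2.0 / om ** 2
                H = np.where(bad[:, None, None], H + prior[None] +
                             np.eye(d)[None] * 1.0, H)
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        # trust region: cap the per-subject Newton step length
        norm = np.linalg.norm(step, axis=1)
        step = step * np.where(norm > 2.0, 2.0 / np.maximum(norm, 2.0),
                               1.0)[:, None]
        # backtracking, vectorized per subject
        scale = np.ones(n)
        for _ls in range(10):
            trial = eta.copy()
            for k, dim in enumerate(dims):
                trial[:, dim] = np.clip(eta[:, dim] - scale * step[:, k],
                                        -eta_cap, eta_cap)
            f_new = fun(trial)
            worse = f_new > f0 + 1e-12
            if not np.any(worse):
                break
            scale = np.where(worse, scale * 0.5, scale)
        scale = np.where(worse, 0.0, scale)  # reject steps that never improved
        for k, dim in enumerate(dims):
            eta[:, dim] = np.clip(eta[:, dim] - scale * step[:, k],
                                  -eta_cap, eta_cap)
        if np.max(np.abs(g)) < tol or np.max(np.abs(step * scale[:, None])) < 1e-10:
            break
    with np.errstate(all="ignore"):
        f0, g, H = _grad_hess(fun, eta, dims)
        H = np.where(np.isfinite(H), H, 0.0)
    # polish the (rare) subjects whose Newton run stalled short of the mode
    stalled = np.nonzero(np.max(np.abs(g), axis=1) > 1e-3)[0]
    if 0 < stalled.size <= max(8, n // 10):
        for i in stalled:
            def g_i(e_free, i=i):
                e = eta.copy()
                for k, dim in enumerate(dims):
                    e[i, dim] = e_free[k]
                return float(fun(e)[i])
            res = optimize.minimize(g_i, eta[i, dims], method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxfev": 400})
            if res.fun < f0[i]:
                for k, dim in enumerate(dims):
                    eta[i, dim] = res.x[k]
        with np.errstate(all="ignore"):
            f0, g, H = _grad_hess(fun, eta, dims)
            H = np.where(np.isfinite(H), H, 0.0)
    return eta, f0, H


def marginal_neg2ll(
    subjects: Sequence[SubjectRecord] | Design,
    pop: PopulationModel,
    eta0: Optional[np.ndarray] = None,
    return_etas: bool = False,
    agq_nodes: int = 1,
):
    """OFV = -2 log marginal likelihood by Laplace approximation at the
    per-subject posterior mode, optionally refined by adaptive
    Gauss-Hermite quadrature centred there (``agq_nodes`` per dimension;
    1 recovers plain Laplace).

    Per subject (Laplace):
    OFV_i = G(eta_hat) + ln|Omega| + ln det(H_G(eta_hat)/2),
    where G is the joint -2 log density (residual + prior quadratic form)
    and H_G its Hessian at the posterior mode.  With all omegas zero this
    reduces to the fixed-eta Gaussian -2 log likelihood at eta = 0.
    """
    design = subjects if isinstance(subjects, Design) else Design(subjects)
    dims = _active_dims(pop)
    eta, g_mode, H = _posterior_modes(design, pop, eta0=eta0)
    ofv_i = g_mode.copy()
    if dims:
        log_det_omega = 0.0
        for dim in dims:
            om = pop.omega_cl if dim == 0 else pop.omega_v
            log_det_omega += 2.0 * math.log(om)
        # eigenvalue-floored log-determinant: the curvature at a true mode
        # is at least the prior's, so floor there to keep saddle-point
        # trial evaluations from injecting huge negative terms
        eigvals, eigvecs = np.linalg.eigh(H / 2.0)
        floor = min((1.0 / pop.omega_cl ** 2 if pop.omega_cl > 0 else np.inf),
                    (1.0 / pop.omega_v ** 2 if pop.omega_v > 0 else np.inf))
        eigvals = np.maximum(eigvals, 1e-3 * floor)
        if agq_nodes > 1:
            ofv_i = _agq_ofv(design, pop, eta, eigvals, eigvecs, dims,
                             agq_nodes) + log_det_omega
        else:
            ofv_i = ofv_i + log_det_omega + np.sum(np.log(eigvals), axis=1)
    if not np.all(np.isfinite(ofv_i)):
        bad = [design.subjects[i].subject_id
               for i in np.nonzero(~np.isfinite(ofv_i))[0]]
        raise FloatingPointError(
            f"non-finite likelihood for subjects {bad}")
    total = float(ofv_i.sum())
    if return_etas:
        return total, eta
    return total


def _agq_ofv(design: Design, pop: PopulationModel, eta: np.ndarray,
             eigvals: np.ndarray, eigvecs: np.ndarray, dims: list[int],
             nodes: int) -> np.ndarray:
    """-2 log of the integral by adaptive Gauss-Hermite around the mode.

    The quadrature Gaussian is N(eta_hat, Sigma) with Sigma^-1 = H_G/2
    (the Laplace curvature); with one node this reduces to Laplace.
    Returns the per-subject value excluding the ln|Omega| prior term.
    """
    d = len(dims)
    # probabilists' Hermite rule: int f(z) exp(-z^2/2) dz ~ sum w_j f(z_j)
    z, w = np.polynomial.hermite_e.hermegauss(nodes)
    zgrids = np.meshgrid(*([z] * d), indexing="ij")
    wgrids = np.meshgrid(*([w] * d), indexing="ij")
    zs = np.stack([g.ravel() for g in zgrids], axis=1)       # (K, d)
    log_w = np.sum(np.log(np.stack([g.ravel() for g in wgrids], axis=1)),
                   axis=1)                                   # (K,)

    # Sigma = (H/2)^-1 = V diag(1/lam) V'; L = V diag(lam^-1/2)
    L = eigvecs * (1.0 / np.sqrt(eigvals))[:, None, :]       # (n, d, d)
    half_logdet_sigma = -0.5 * np.sum(np.log(eigvals), axis=1)

    logterms = np.empty((zs.shape[0], design.n))
    for k in range(zs.shape[0]):
        delta = np.einsum("nij,j->ni", L, zs[k])             # (n, d)
        e = eta.copy()
        for kk, dim in enumerate(dims):
            e[:, dim] = eta[:, dim] + delta[:, kk]
        G_k = _joint_neg2ll(design, pop, e)
        logterms[k] = log_w[k] + 0.5 * (zs[k] @ zs[k]) - 0.5 * G_k
    mmax = logterms.max(axis=0)
    log_integral = half_logdet_sigma + mmax + np.log(
        np.sum(np.exp(logterms - mmax), axis=0))
    # marginal_i = (2pi)^{-d/2} |Omega|^{-1/2} * integral; the |Omega| term
    # is added by the caller
    return d * math.log(2.0 * math.pi) - 2.0 * log_integral

@dataclass
class FitResult:
    ofv: float
    estimates: PopulationModel
    theta: dict
    rse: dict
    ebes: np.ndarray                # (n_subjects, 2)
    subject_ids: list[str]
    cwres: pd.DataFrame             # subject_id, time, dv, ipred, cwres
    shrinkage: dict
    converged: bool
    n_params: int
    fixed: frozenset = frozenset()


@dataclass
class ComparisonResult:
    delta_ofv: float
    delta_params: int
    p_value: float
    delta_aic: float
    decision: str                   # "accept_complex" / "keep_simple"


@dataclass
class BootstrapResult:
    n_replicates: int
    summary: pd.DataFrame           # parameter, median, ci_low, ci_high
    replicates: pd.DataFrame


def _free_params(start: PopulationModel, fixed: frozenset) -> list[str]:
    names = []
    for p in _POSITIVE_PARAMS:
        if p in fixed:
            continue
        if getattr(start, p) == 0:   # structurally absent variance term
            continue
        names.append(p)
    for i, eff in enumerate(start.covariate_effects):
        if not eff.fixed:
            names.append(f"theta_{i}")
    return names


def _pack(pop: PopulationModel, names: list[str]) -> np.ndarray:
    x = []
    for nm in names:
        if nm.startswith("theta_"):
            x.append(pop.covariate_effects[int(nm[6:])].theta)
        else:
            x.append(math.log(getattr(pop, nm)))
    return np.array(x)


def _unpack(x: np.ndarray, template: PopulationModel,
            names: list[str]) -> PopulationModel:
    changes = {}
    effects = [CovariateEffect(**vars(e)) for e in template.covariate_effects]
    for nm, val in zip(names, x):
        if nm.startswith("theta_"):
            effects[int(nm[6:])].theta = float(val)
        else:
            changes[nm] = float(np.exp(np.clip(val, -20, 20)))
    return template.copy(covariate_effects=effects, **changes)


def fit(
    subjects: Sequence[SubjectRecord] | Design,
    start: PopulationModel,
    fixed: frozenset | set = DEFAULT_FIXED,
    n_starts: int = 3,
    seed: int = 0,
    compute_rse: bool = True,
    maxfev: int = 4000,
) -> FitResult:
    """Maximum (Laplace-approximate) marginal likelihood population fit.

    Optimizes the unmasked parameters on the log scale with Nelder-Mead,
    using ``n_starts`` jittered starting points to mitigate local minima.
    Empirical Bayes estimates are the per-subject posterior modes at the
    final parameters; RSE comes from the observed-information Hessian.
    """
    design = subjects if isinstance(subjects, Design) else Design(subjects)
    fixed = frozenset(fixed)
    names = _free_params(start, fixed)
    eta_ws = {"eta": None}

    def objective(x: np.ndarray) -> float:
        try:
            pop = _unpack(x, start, names)
            ofv, eta = marginal_neg2ll(design, pop, eta0=eta_ws["eta"],
                                       return_etas=True)
            eta_ws["eta"] = eta
            return ofv
        except (FloatingPointError, ValueError):
            return 1e12

    if not names:
        ofv, eta = marginal_neg2ll(design, start, return_etas=True)
        return _finalize(design, start, {}, {}, eta, ofv, True, fixed)

    rng = np.random.default_rng(seed)
    x0 = _pack(start, names)
    best = None
    def run_nm(xk: np.ndarray, step: float, budget: int):
        # explicit initial simplex: Nelder-Mead's default step for a
        # coordinate at exactly 0 (fresh covariate thetas) is ~2.5e-4,
        # far too small to escape the flat region around no-effect
        simplex = np.vstack([xk] + [xk + step * np.eye(len(xk))[i]
                                    for i in range(len(xk))])
        return optimize.minimize(
            objective, xk, method="Nelder-Mead",
            options={"xatol": 2e-3, "fatol": 5e-3, "maxfev": budget,
                     "adaptive": len(xk) > 4,
                     "initial_simplex": simplex})

    for k in range(max(1, n_starts)):
        xk = x0 if k == 0 else x0 + rng.normal(0, 0.2, size=x0.shape)
        res = run_nm(xk, 0.25, maxfev)
        # restart with a fresh simplex: guards against premature
        # simplex collapse in higher-dimensional searches
        res2 = run_nm(res.x, 0.1, max(maxfev // 2, 200))
        if res2.fun < res.fun:
            res = res2
        if best is None or res.fun < best.fun:
            best = res
    x_hat = best.x
    pop_hat = _unpack(x_hat, start, names)
    ofv, eta = marginal_neg2ll(design, pop_hat, eta0=eta_ws["eta"],
                               return_etas=True)

    rse = {}
    if compute_rse:
        rse = _rse_from_hessian(objective, x_hat, names)

    theta = {nm: (pop_hat.covariate_effects[int(nm[6:])].theta
                  if nm.startswith("theta_") else getattr(pop_hat, nm))
             for nm in names}
    return _finalize(design, pop_hat, theta, rse, eta, ofv,
                     bool(best.success), fixed)


def _rse_from_hessian(objective, x_hat, names, h: float = 0.15) -> dict:
    """RSE%% from the finite-difference Hessian of the OFV.

    Cov = 2 * H^-1 (OFV is -2 log L).  For log-scale parameters the SE of
    log(theta) is directly the relative SE of theta.  The step is wide
    (15% on the log scale) so the curvature reflects the likelihood
    envelope rather than local mode-search roughness; the bootstrap is
    the reliability tool of record for sparse designs.
    """
    p = len(x_hat)
    H = np.zeros((p, p))
    f0 = objective(x_hat)
    fp = np.empty(p)
    fm = np.empty(p)
    for a in range(p):
        xa = x_hat.copy()
        xa[a] += h
        fp[a] = objective(xa)
        xa[a] -= 2 * h
        fm[a] = objective(xa)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h ** 2
    for a in range(p):
        for b in range(a + 1, p):
            xab = x_hat.copy()
            xab[[a, b]] += h
            fpp = objective(xab)
            xab[[a, b]] -= 2 * h
            fmm = objective(xab)
            H[a, b] = H[b, a] = (
                fpp - fp[a] - fp[b] + 2 * f0 - fm[a] - fm[b] + fmm
            ) / (2 * h ** 2)
    rse = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for nm, s, xv in zip(names, se, x_hat):
            if nm.startswith("theta_"):
                rse[nm] = 100.0 * s / abs(xv) if xv != 0 else float("inf")
            else:
                rse[nm] = 100.0 * s
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; RSE unavailable")
    return rse


def _finalize(design, pop, theta, rse, eta, ofv, converged, fixed):
    cwres_df = compute_cwres(design, pop, eta)
    shrink = {}
    if pop.omega_cl > 0:
        shrink["eta_cl"] = eta_shrinkage(eta[:, 0], pop.omega_cl)
    if pop.omega_v > 0:
        shrink["eta_v"] = eta_shrinkage(eta[:, 1], pop.omega_v)
    return FitResult(
        ofv=ofv, estimates=pop, theta=theta, rse=rse, ebes=eta,
        subject_ids=[s.subject_id for s in design.subjects],
        cwres=cwres_df, shrinkage=shrink, converged=converged,
        n_params=len(theta), fixed=fixed)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def compute_cwres(design: Design, pop: PopulationModel,
                  eta: np.ndarray) -> pd.DataFrame:
    """Conditional weighted residuals by FOCE linearization around the EBEs.

    y ~ N(f(eta_hat) - J eta_hat, J Omega J' + diag(residual var)), and
    CWRES = Cov^{-1/2} (y - E[y]) using the symmetric matrix square root.
    """
    dims = _active_dims(pop)
    omega = np.diag([
        (pop.omega_cl if d == 0 else pop.omega_v) ** 2 for d in dims])
    rows = []
    h = 1e-4
    f_all = design.predictions(pop, eta)
    for i, subj in enumerate(design.subjects):
        m = design.obs_mask[i]
        f0 = f_all[i, m]
        y = design.y[i, m]
        t = design.t_obs[i, m]
        var = (f0 * pop.sigma_prop) ** 2 + pop.sigma_add ** 2
        if dims:
            J = np.zeros((f0.size, len(dims)))
            for k, dim in enumerate(dims):
                ep = eta.copy()
                ep[i, dim] += h
                em = eta.copy()
                em[i, dim] -= h
                J[:, k] = (design.predictions(pop, ep)[i, m]
                           - design.predictions(pop, em)[i, m]) / (2 * h)
            cov = J @ omega @ J.T + np.diag(var)
            mean = f0 - J @ eta[i, dims]
            w, V = np.linalg.eigh(cov)
            inv_sqrt = V @ np.diag(1.0 / np.sqrt(np.maximum(w, 1e-12))) @ V.T
            cw = inv_sqrt @ (y - mean)
        else:
            cw = (y - f0) / np.sqrt(var)
        for j in range(f0.size):
            rows.append((subj.subject_id, t[j], y[j], f0[j], cw[j]))
    return pd.DataFrame(rows, columns=["subject_id", "time", "dv",
                                       "ipred", "cwres"])


def cwres_flag(fit_result: FitResult, threshold: float = 3.0) -> pd.DataFrame:
    """Observations with |CWRES| above the threshold (outlier candidates)."""
    df = fit_result.cwres
    return df[np.abs(df["cwres"]) > threshold].reset_index(drop=True)


def eta_shrinkage(ebes: np.ndarray, omega: float) -> float:
    """Percent shrinkage of the EBE distribution: 100 (1 - SD(EBE)/omega)."""
    if not omega > 0:
        raise ValueError("omega must be positive")
    sd = float(np.sqrt(np.mean(np.square(ebes))))
    return 100.0 * (1.0 - sd / omega)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def _lrt_threshold(level: float, df: int) -> float:
    # chi-square quantile rounded to the conventionally printed 2 decimals,
    # so the inclusive boundary Delta OFV <= -3.84 behaves as printed
    return round(float(stats.chi2.ppf(1.0 - level, df)), 2)


def lrt_compare(fit_simple: FitResult, fit_complex: FitResult,
                alpha_mode: str = "forward") -> ComparisonResult:
    """Likelihood-ratio comparison of nested fits.

    forward:  accept the complex model iff Delta OFV <= -3.84 (df-scaled,
    p = 0.05); backward: retain the extra parameter only if its deletion
    would raise the OFV by more than 6.63 (p = 0.01).
    """
    df = fit_complex.n_params - fit_simple.n_params
    if df <= 0:
        raise ValueError("complex model must have more parameters")
    delta_ofv = fit_complex.ofv - fit_simple.ofv
    p_value = float(stats.chi2.sf(max(-delta_ofv, 0.0), df))
    delta_aic = (fit_complex.ofv + 2 * fit_complex.n_params
                 - fit_simple.ofv - 2 * fit_simple.n_params)
    if alpha_mode == "forward":
        accept = delta_ofv <= -_lrt_threshold(0.05, df)
    elif alpha_mode == "backward":
        accept = delta_ofv <= -_lrt_threshold(0.01, df)
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    return ComparisonResult(
        delta_ofv=delta_ofv, delta_params=df, p_value=p_value,
        delta_aic=delta_aic,
        decision="accept_complex" if accept else "keep_simple")


def aic_compare(fit_a: FitResult, fit_b: FitResult) -> ComparisonResult:
    """Select the alternative (b) iff its AIC is lower by at least 2."""
    aic_a = fit_a.ofv + 2 * fit_a.n_params
    aic_b = fit_b.ofv + 2 * fit_b.n_params
    delta_aic = aic_b - aic_a
    return ComparisonResult(
        delta_ofv=fit_b.ofv - fit_a.ofv,
        delta_params=fit_b.n_params - fit_a.n_params,
        p_value=float("nan"), delta_aic=delta_aic,
        decision="accept_complex" if delta_aic <= -2.0 else "keep_simple")


# ---------------------------------------------------------------------------
# Stepwise covariate search
# ---------------------------------------------------------------------------

@dataclass
class CovariateCandidate:
    parameter: str
    covariate: str
    form: str = POWER


def stepwise_covariates(
    subjects: Sequence[SubjectRecord] | Design,
    base_fit: FitResult,
    candidates: Sequence[CovariateCandidate],
    n_starts: int = 1,
    maxfev: int = 2000,
):
    """Forward inclusion (p=0.05) / backward deletion (p=0.01) search.

    Continuous covariates are centred/normalized on the cohort median.
    Returns the final FitResult and a trace DataFrame with one row per
    tested relation (phase, relation, delta OFV, decision) plus the
    IIV-variance reduction of each retained relation.
    """
    design = subjects if isinstance(subjects, Design) else Design(subjects)
    fwd_t = _lrt_threshold(0.05, 1)
    bwd_t = _lrt_threshold(0.01, 1)

    usable: list[CovariateCandidate] = []
    refs: dict[str, float] = {}
    for cand in candidates:
        x = design.covariate_values(cand.covariate)
        if np.all(np.isnan(x)):
            warnings.warn(f"covariate {cand.covariate} missing for all "
                          "subjects; candidate skipped")
            continue
        refs[cand.covariate] = float(np.nanmedian(x))
        usable.append(cand)

    def fit_with(effects: list[CovariateEffect], start_model) -> FitResult:
        model = start_model.copy(covariate_effects=effects)
        return fit(design, model, fixed=base_fit.fixed, n_starts=n_starts,
                   compute_rse=False, maxfev=maxfev)

    trace_rows = []
    current = base_fit
    retained: list[CovariateEffect] = []
    remaining = list(usable)
    step = 0
    while remaining:
        step += 1
        results = []
        for cand in remaining:
            ref = (refs[cand.covariate]
                   if cand.form != CATEGORICAL else 0.0)
            eff = CovariateEffect(parameter=cand.parameter,
                                  covariate=cand.covariate, form=cand.form,
                                  theta=0.0, ref=ref)
            trial = fit_with(retained + [eff], current.estimates)
            d_ofv = trial.ofv - current.ofv
            results.append((d_ofv, cand, eff, trial))
            trace_rows.append((step, "forward",
                               f"{cand.covariate}->{cand.parameter}",
                               cand.form, d_ofv, ""))
        results.sort(key=lambda r: r[0])
        d_best, cand_best, eff_best, fit_best = results[0]
        if d_best <= -fwd_t:
            retained.append(CovariateEffect(
                parameter=eff_best.parameter, covariate=eff_best.covariate,
                form=eff_best.form,
                theta=fit_best.estimates.covariate_effects[-1].theta,
                ref=eff_best.ref))
            current = fit_best
            remaining.remove(cand_best)
            for r in trace_rows:
                if (r[0] == step and
                        r[2] == f"{cand_best.covariate}->{cand_best.parameter}"):
                    trace_rows[trace_rows.index(r)] = r[:5] + ("included",)
        else:
            break

    # backward deletion at p = 0.01
    changed = True
    while changed and retained:
        changed = False
        step += 1
        for k, eff in enumerate(list(retained)):
            reduced_effects = [e for j, e in enumerate(retained) if j != k]
            reduced = fit_with(reduced_effects, current.estimates)
            d_removal = reduced.ofv - current.ofv
            keep = d_removal > bwd_t
            trace_rows.append((step, "backward",
                               f"{eff.covariate}->{eff.parameter}",
                               eff.form, d_removal,
                               "kept" if keep else "removed"))
            if not keep:
                retained.pop(k)
                current = reduced
                changed = True
                break

    iiv_reduction = {}
    for eff in retained:
        om_name = "omega_cl" if eff.parameter == "cl" else "omega_v"
        om_base = getattr(base_fit.estimates, om_name)
        om_fin = getattr(current.estimates, om_name)
        if om_base > 0:
            iiv_reduction[f"{eff.covariate}->{eff.parameter}"] = \
                100.0 * (1.0 - om_fin ** 2 / om_base ** 2)

    trace = pd.DataFrame(trace_rows, columns=[
        "step", "phase", "relation", "form", "delta_ofv", "decision"])
    return current, trace, iiv_reduction


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    subjects: Sequence[SubjectRecord],
    start: PopulationModel,
    fixed: frozenset | set = DEFAULT_FIXED,
    n: int = 2000,
    seed: int = 0,
    maxfev: int = 2000,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, percentile CI95."""
    rng = np.random.default_rng(seed)
    subjects = list(subjects)
    names = _free_params(start, frozenset(fixed))
    rows = []
    for rep in range(n):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        resampled = [subjects[i] for i in idx]
        res = fit(resampled, start, fixed=fixed, n_starts=1,
                  compute_rse=False, maxfev=maxfev)
        rows.append({nm: res.theta[nm] for nm in names} | {"rep": rep})
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "parameter": names,
        "median": [reps[nm].median() for nm in names],
        "ci_low": [reps[nm].quantile(0.025) for nm in names],
        "ci_high": [reps[nm].quantile(0.975) for nm in names],
    })
    return BootstrapResult(n_replicates=n, summary=summary, replicates=reps)
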