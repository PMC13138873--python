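"""External-validation metrics and prediction-corrected visual predictive checks.

MPE and RMSE are computed on the log scale and back-transformed to
percentages:

    MPE(%)  = 100 * (exp(mean(ln DV - ln IPRED)) - 1)
    RMSE(%) = 100 * sqrt(exp(mean((ln DV - ln IPRED)^2)) - 1)

with the MPE CI95 from a Student-t interval on the log differences,
back-transformed the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PopulationModel, SubjectRecord
from .poppk_fit import Design


@dataclass
class ValidationMetrics:
    mpe_pct: float
    mpe_ci95: tuple[float, float]
    rmse_pct: float
    n_pairs: int


@dataclass
class VpcResult:
    table: pd.DataFrame   # bin, t_mid, percentile, observed, sim_lo, sim_hi
    n_sim: int
    bins: int


def _log_diffs(dv_list, ipred_list) -> np.ndarray:
    dv = np.asarray(dv_list, float)
    ipred = np.asarray(ipred_list, float)
    if dv.shape != ipred.shape:
        raise ValueError("DV and IPRED lists must have equal length")
    if np.any(dv <= 0) or np.any(ipred <= 0):
        raise ValueError("MPE/RMSE require strictly positive DV and IPRED")
    return np.log(dv) - np.log(ipred)


def mpe(dv_list, ipred_list) -> ValidationMetrics:
    """Mean prediction error (%) with its CI95, log scale back-transformed."""
    d = _log_diffs(dv_list, ipred_list)
    m = float(np.mean(d))
    if d.size > 1:
        half = stats.t.ppf(0.975, d.size - 1) * np.std(d, ddof=1) / np.sqrt(d.size)
    else:
        half = float("inf")
    to_pct = lambda x: 100.0 * (np.exp(x) - 1.0)
    return ValidationMetrics(
        mpe_pct=to_pct(m),
        mpe_ci95=(to_pct(m - half), to_pct(m + half)),
        rmse_pct=rmse(dv_list, ipred_list),
        n_pairs=d.size)


def rmse(dv_list, ipred_list) -> float:
    """Root-mean-squared log-scale prediction error, as a percentage."""
    d = _log_diffs(dv_list, ipred_list)
    return float(100.0 * np.sqrt(np.exp(np.mean(d ** 2)) - 1.0))


def _time_after_dose(design: Design) -> np.ndarray:
    """Time since the most recent dose for every retained observation."""
    tad = np.full_like(design.t_obs, np.nan)
    for i, subj in enumerate(design.subjects):
        dt = np.array([d.time for d in subj.doses])
        for j in np.nonzero(design.obs_mask[i])[0]:
            prior = dt[dt <= design.t_obs[i, j]]
            tad[i, j] = (design.t_obs[i, j] - prior.max()
                         if prior.size else design.t_obs[i, j])
    return tad


def simulate_observations(design: Design, pop: PopulationModel,
                          rng: np.random.Generator) -> np.ndarray:
    """One replicate dataset: new etas and residual errors on the design grid."""
    n = design.n
    eta = np.zeros((n, 2))
    if pop.omega_cl > 0:
        eta[:, 0] = rng.normal(0.0, pop.omega_cl, n)
    if pop.omega_v > 0:
        eta[:, 1] = rng.normal(0.0, pop.omega_v, n)
    f = design.predictions(pop, eta)
    eps_p = rng.normal(0.0, pop.sigma_prop, f.shape)
    eps_a = rng.normal(0.0, pop.sigma_add, f.shape)
    return f * (1.0 + eps_p) + eps_a


def pcvpc(
    subjects: Sequence[SubjectRecord] | Design,
    pop: PopulationModel,
    n_sim: int = 500,
    bins: int = 10,
    seed: int = 0,
    percentiles: tuple = (5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected VPC binned on time after dose.

    Observed and simulated values are multiplied by (bin median population
    prediction / own population prediction); observed 5/50/95th percentiles
    are compared against the simulation-derived 95% CIs of the same
    percentiles per bin.  Bins hold approximately equal observation counts.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    design = subjects if isinstance(subjects, Design) else Design(subjects)
    rng = np.random.default_rng(seed)

    pred = design.predictions(pop, np.zeros((design.n, 2)))   # PRED (eta=0)
    mask = design.obs_mask
    tad = _time_after_dose(design)[mask]
    y = design.y[mask]
    pred_f = np.maximum(pred[mask], 1e-12)

    edges = np.unique(np.quantile(tad, np.linspace(0, 1, bins + 1)))
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
    n_bins = len(edges) - 1

    bin_median_pred = np.empty(n_bins)
    keep = []
    for b in range(n_bins):
        sel = bin_idx == b
        if not np.any(sel):
            warnings.warn(f"empty pcVPC bin {b}; dropped")
            bin_median_pred[b] = np.nan
            continue
        bin_median_pred[b] = np.median(pred_f[sel])
        keep.append(b)

    correction = bin_median_pred[bin_idx] / pred_f
    pc_obs = y * correction

    sims = np.empty((n_sim, y.size))
    for s in range(n_sim):
        y_sim = simulate_observations(design, pop, rng)[mask]
        sims[s] = y_sim * correction

    rows = []
    for b in keep:
        sel = bin_idx == b
        t_mid = float(np.median(tad[sel]))
        for p in percentiles:
            obs_p = float(np.percentile(pc_obs[sel], p))
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            rows.append((b, t_mid, p, obs_p,
                         float(np.percentile(sim_p, 2.5)),
                         float(np.percentile(sim_p, 50.0)),
                         float(np.percentile(sim_p, 97.5))))
    table = pd.DataFrame(rows, columns=[
        "bin", "tad_mid", "percentile", "observed",
        "sim_lo", "sim_mid", "sim_hi"])
    return VpcResult(table=table, n_sim=n_sim, bins=n_bins)


def plot_pcvpc(result: VpcResult, path: Optional[str] = None):
    """Render the pcVPC as the usual percentile-band figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for p, color in zip((5.0, 50.0, 95.0), ("tab:blue", "tab:red", "tab:blue")):
        sub = result.table[result.table["percentile"] == p]
        if sub.empty:
            continue
        ax.fill_between(sub["tad_mid"], sub["sim_lo"], sub["sim_hi"],
                        alpha=0.25, color=color)
        ax.plot(sub["tad_mid"], sub["observed"], "o-", color=color,
                label=f"observed P{p:g}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
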