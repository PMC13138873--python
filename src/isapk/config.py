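"""Pipeline configuration and orchestration.

A run is described by a plain dict (usually loaded from YAML) with a
global ``seed``, an ``out_dir``, the ordered ``stages`` to execute and
one parameter block per stage.  Every stage draws its randomness from a
dedicated stream derived from the global seed and the stage name, so
stages are independently reproducible; every output directory carries a
``metadata.json`` with the seed and a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    dataset_io,
    individual_bayes,
    model_eval,
    pkpd_analysis,
    poppk_fit,
    synthetic_cohort,
    virtual_tdm,
)
from .datatypes import PopulationModel

log = logging.getLogger("isapk")

ALL_STAGES = ["simulate-cohort", "fit", "evaluate", "bayes-exposure",
              "pkpd", "virtual-tdm"]

REQUIRED_BLOCKS = {
    "simulate-cohort": "cohort",
    "fit": "fit",
    "evaluate": "evaluate",
    "bayes-exposure": "bayes",
    "pkpd": "pkpd",
    "virtual-tdm": "tdm",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def default_config(seed: int = 0, out_dir: str = "results") -> dict:
    return {
        "seed": seed,
        "out_dir": out_dir,
        "stages": list(ALL_STAGES),
        "cohort": {"n_subjects": 41},
        "fit": {"start": {"tvcl": 2.0, "tvv": 400.0, "omega_cl": 0.3,
                          "omega_v": 0.3, "sigma_prop": 0.2,
                          "sigma_add": 0.5},
                "n_starts": 3},
        "evaluate": {"n_sim": 200, "bins": 8},
        "bayes": {},
        "pkpd": {},
        "tdm": {"n": 10000, "dose": 200.0,
                "half_life_bounds": [40.0, 400.0],
                "strategies": ["none", "proportional_cmin",
                               "mipd_cmin", "mipd_auc"]},
    }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("missing config block 'seed'")
    for stage in config.get("stages", ALL_STAGES):
        if stage not in ALL_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        block = REQUIRED_BLOCKS[stage]
        if block not in config:
            raise ConfigError(f"missing config block {block!r}")


def _model_from_dict(d: Optional[dict]) -> PopulationModel:
    return PopulationModel(**d) if d else PopulationModel()


def run_pipeline(config: dict, subjects=None, truth=None) -> dict:
    """Execute the configured stages in order; returns artifact paths."""
    validate_config(config)
    out = Path(config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    meta = {"seed": seed, "config_hash": _config_hash(config)}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    artifacts: dict[str, str] = {}
    state: dict = {"subjects": subjects, "truth": truth}

    for stage in config.get("stages", ALL_STAGES):
        log.info("stage %s", stage)
        try:
            _STAGES[stage](config, state, out, artifacts)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {stage!r} failed: {e}") from e
    return artifacts


def _require_subjects(config, state, out):
    if state["subjects"] is None:
        data = out / "data.csv"
        if not data.exists():
            raise ConfigError("no cohort available; run simulate-cohort "
                              "first or provide a dataset")
        state["subjects"] = dataset_io.read_dataset(data)
    return state["subjects"]


def _stage_simulate(config, state, out, artifacts):
    block = config["cohort"]
    spec = synthetic_cohort.CohortSpec(
        seed=stage_seed(config["seed"], "simulate-cohort"),
        **{k: v for k, v in block.items() if k != "seed"})
    subjects, truth = synthetic_cohort.generate_cohort(spec)
    outcomes = synthetic_cohort.generate_outcomes(
        truth, spec.outcome_model,
        seed=stage_seed(config["seed"], "outcomes"))
    synthetic_cohort.attach_outcomes(subjects, outcomes, truth)
    dataset_io.write_dataset(subjects, out / "data.csv")
    truth.to_csv(out / "truth.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    state.update(subjects=subjects, truth=truth, outcomes=outcomes)
    artifacts["data"] = str(out / "data.csv")
    artifacts["truth"] = str(out / "truth.csv")
    artifacts["outcomes"] = str(out / "outcomes.csv")


def _stage_fit(config, state, out, artifacts):
    subjects = _require_subjects(config, state, out)
    block = config["fit"]
    start = _model_from_dict(block.get("start"))
    res = poppk_fit.fit(
        subjects, start,
        n_starts=int(block.get("n_starts", 1)),
        seed=stage_seed(config["seed"], "fit"),
        maxfev=int(block.get("maxfev", 4000)))
    state["fit"] = res
    report = {
        "ofv": res.ofv,
        "estimates": {k: getattr(res.estimates, k) for k in (
            "tvcl", "tvv", "ka", "f_oral", "omega_cl", "omega_v",
            "sigma_prop", "sigma_add")},
        "rse_pct": res.rse,
        "shrinkage_pct": res.shrinkage,
        "converged": res.converged,
        "seed": stage_seed(config["seed"], "fit"),
    }
    (out / "fit.json").write_text(json.dumps(report, indent=2))
    res.cwres.to_csv(out / "cwres.csv", index=False)
    artifacts["fit"] = str(out / "fit.json")
    artifacts["cwres"] = str(out / "cwres.csv")


def _fitted_model(config, state) -> PopulationModel:
    if state.get("fit") is not None:
        return state["fit"].estimates
    return _model_from_dict(config.get("model"))


def _stage_evaluate(config, state, out, artifacts):
    subjects = _require_subjects(config, state, out)
    block = config["evaluate"]
    pop = _fitted_model(config, state)
    fit_res = state.get("fit")
    if fit_res is not None:
        dv = fit_res.cwres["dv"].to_numpy()
        ipred = np.maximum(fit_res.cwres["ipred"].to_numpy(), 1e-9)
        metrics = model_eval.mpe(dv, ipred)
        (out / "validation.json").write_text(json.dumps({
            "mpe_pct": metrics.mpe_pct, "mpe_ci95": list(metrics.mpe_ci95),
            "rmse_pct": metrics.rmse_pct, "n_pairs": metrics.n_pairs,
        }, indent=2))
        artifacts["validation"] = str(out / "validation.json")
    vpc = model_eval.pcvpc(
        subjects, pop, n_sim=int(block.get("n_sim", 200)),
        bins=int(block.get("bins", 8)),
        seed=stage_seed(config["seed"], "evaluate"))
    vpc.table.to_csv(out / "pcvpc.csv", index=False)
    model_eval.plot_pcvpc(vpc, str(out / "pcvpc.png"))
    artifacts["pcvpc"] = str(out / "pcvpc.csv")


def _stage_bayes(config, state, out, artifacts):
    subjects = _require_subjects(config, state, out)
    pop = _fitted_model(config, state)
    table = individual_bayes.exposure_table(subjects, pop, dates={})
    table.to_csv(out / "exposures.csv", index=False)
    state["exposures"] = table
    artifacts["exposures"] = str(out / "exposures.csv")


def _stage_pkpd(config, state, out, artifacts):
    exposures = state.get("exposures")
    if exposures is None:
        path = out / "exposures.csv"
        if not path.exists():
            raise ConfigError("pkpd stage needs the bayes-exposure output")
        exposures = pd.read_csv(path)
    outcomes = state.get("outcomes")
    if outcomes is None:
        path = out / "outcomes.csv"
        if not path.exists():
            raise ConfigError("pkpd stage needs outcome labels")
        outcomes = pd.read_csv(path)
    merged = exposures.merge(outcomes, on="subject_id").dropna(
        subset=["cmin", "auc"])
    records = [pkpd_analysis.ExposureOutcomeRecord(
        subject_id=r.subject_id, centre=1, cmin=r.cmin, auc=r.auc,
        success=int(r.success), hepatotoxicity=int(r.hepatotoxicity),
        discontinuation=int(r.discontinuation))
        for r in merged.itertuples()]
    results = []
    for exposure in ("cmin", "auc"):
        for outcome in ("success", "hepatotoxicity"):
            try:
                results.append(pkpd_analysis.fit_exposure_outcome(
                    records, exposure=exposure, outcome=outcome))
            except ValueError as e:
                log.warning("pkpd %s~%s skipped: %s", outcome, exposure, e)
    table = pkpd_analysis.results_table(results)
    table.to_json(out / "pkpd.json", orient="records", indent=2)
    # fitted-curve table for plotting
    if results:
        grid = np.linspace(0.5, 10.0, 50)
        curve = pd.DataFrame({"cmin": grid})
        for r in results:
            if r.exposure == "cmin" and not r.separated:
                curve[f"p_{r.outcome}"] = r.probability(grid)
        curve.to_csv(out / "pkpd_curve.csv", index=False)
    artifacts["pkpd"] = str(out / "pkpd.json")


def _stage_tdm(config, state, out, artifacts):
    block = config["tdm"]
    pop = _fitted_model(config, state)
    seed = stage_seed(config["seed"], "virtual-tdm")
    cohort = virtual_tdm.simulate_cohort(
        n=int(block.get("n", 10000)), pop=pop,
        half_life_bounds=tuple(block.get("half_life_bounds", (40.0, 400.0))),
        dose=float(block.get("dose", 200.0)), seed=seed)
    summaries = []
    for kind in block.get("strategies", ["none", "proportional_cmin",
                                         "mipd_cmin", "mipd_auc"]):
        strategy = virtual_tdm.TdmStrategy(
            kind=kind,
            target_range=(virtual_tdm.AUC_TARGET_RANGE
                          if kind == "mipd_auc"
                          else virtual_tdm.CMIN_TARGET_RANGE))
        _, summary = virtual_tdm.apply_strategy(cohort, strategy, pop)
        summaries.append(vars(summary))
    (out / "tdm_summary.json").write_text(
        json.dumps({"seed": seed, "strategies": summaries}, indent=2))
    cohort.to_frame().to_csv(out / "tdm_cohort.csv", index=False)
    artifacts["tdm"] = str(out / "tdm_summary.json")


_STAGES = {
    "simulate-cohort": _stage_simulate,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
    "bayes-exposure": _stage_bayes,
    "pkpd": _stage_pkpd,
    "virtual-tdm": _stage_tdm,
}
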