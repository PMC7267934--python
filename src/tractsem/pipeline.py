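"""The full analysis pipeline: measurement models, their comparison, and
the regularized watershed MIMIC, driven by one structured configuration.

Stages (each logged with its parameters):

1. load a subject table (CSV) or simulate one,
2. one-factor CFA of the four intelligence indices,
3. two-factor (fluid/crystallized) CFA and BIC comparison,
4. elastic-net penalized MIMIC path over the lambda grid on the watershed
   structure (10 tract FA columns + age as causes),
5. BIC selection, trajectory export, and a single JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .estimators import DEFAULT_ASSIGNMENT, ElasticNetMimic, MimicSEM
from .simulate import (DEFAULT_TRUE_GAMMA, INDICATORS, TRACTS, SemSimConfig,
                       simulate_subject_table)
from .tableio import read_study_table

__all__ = ["run_pipeline", "default_config"]

log = logging.getLogger("tractsem")


def default_config() -> dict:
    return {
        "seed": 0,
        "table": None,  # path to a CSV; None -> simulate
        "simulate": {},  # SemSimConfig overrides
        "model": {
            "assignment": {k: list(v) for k, v in DEFAULT_ASSIGNMENT.items()},
            "predictors": list(TRACTS) + ["age"],
        },
        "regularization": {
            "alpha": 0.5,
            "sparsify_tol": 1e-3,
            "penalize_age": True,
            "lambda_grid": None,  # None -> 35 values from 0 to 0.35
        },
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("load-data")
def _load(config):
    if config.get("table"):
        table = read_study_table(config["table"], aliases=config.get("aliases"))
        log.info("loaded %d subjects from %s (dropped %d)", len(table),
                 config["table"], table.attrs.get("n_dropped", 0))
        return table, None
    sim_kw = dict(config.get("simulate") or {})
    sim_kw.setdefault("seed", config.get("seed", 0))
    sim = SemSimConfig(**sim_kw)
    table, truth = simulate_subject_table(sim)
    log.info("simulated %d subjects (seed %s)", sim.n, sim.seed)
    return table, truth


@_stage("cfa")
def _cfa(table, assignment):
    est = MimicSEM(assignment=assignment, predictors=()).fit(table)
    log.info("CFA %s: chi2=%.3f df=%d BIC=%.3f", list(assignment),
             est.chi_square_, est.df_, est.bic_)
    return est


@_stage("regularized-mimic")
def _mimic(table, model_cfg, reg_cfg, chi2_multiplier="nm1"):
    est = ElasticNetMimic(
        assignment=model_cfg["assignment"],
        predictors=tuple(model_cfg["predictors"]),
        lambda_grid=reg_cfg.get("lambda_grid"),
        alpha=reg_cfg.get("alpha", 0.5),
        sparsify_tol=reg_cfg.get("sparsify_tol", 1e-3),
        penalize_age=reg_cfg.get("penalize_age", True),
        chi2_multiplier=chi2_multiplier,
    ).fit(table)
    log.info("selected lambda=%.4f with %d nonzero edges",
             est.selected_lambda_, len(est.selected_edges_))
    return est


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Execute the pipeline; returns (and optionally writes) the report.

    Any stage failure aborts with a stage-named error; outputs produced by
    earlier stages are preserved in ``out_dir`` when given.
    """
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(cfg), "stages": {}}

    table, truth = _load(cfg)
    if out_dir is not None and cfg.get("table") is None:
        table.to_csv(out_dir / "table.csv", index=False)

    assignment = cfg["model"]["assignment"]
    one_factor = _cfa(table, {"g": list(INDICATORS)})
    report["stages"]["one_factor_cfa"] = one_factor.result_.to_dict()
    two_factor = _cfa(table, assignment)
    report["stages"]["two_factor_cfa"] = two_factor.result_.to_dict()
    report["stages"]["bic_comparison"] = {
        "one_factor_bic": one_factor.bic_,
        "two_factor_bic": two_factor.bic_,
        "preferred": "two_factor" if two_factor.bic_ < one_factor.bic_ else "one_factor",
    }
    if out_dir is not None:
        _dump(report, out_dir / "report.json")

    mimic = _mimic(table, cfg["model"], cfg["regularization"])
    report["stages"]["regularized_mimic"] = {
        "selected_lambda": mimic.selected_lambda_,
        "selected_edges": [
            {"predictor": p, "latent": l, "coefficient": c}
            for p, l, c in mimic.selected_edges_
        ],
        "selected_edges_raw_scale": [
            {"predictor": p, "latent": l, "coefficient": c}
            for p, l, c in mimic.selected_edges_raw_
        ],
        "bic_path": mimic.bic_path_.tolist(),
        "n_nonzero_path": mimic.n_nonzero_path_.tolist(),
        "lambda_grid": [e.lam for e in mimic.path_.entries],
    }
    if truth is not None:
        true_gamma = (cfg.get("simulate") or {}).get("true_gamma") or DEFAULT_TRUE_GAMMA
        report["stages"]["simulation_truth"] = {
            "true_edges": [
                {"predictor": p, "latent": l, "coefficient": float(v)}
                for (p, l), v in true_gamma.items()
            ],
        }
    if out_dir is not None:
        from .penalized import write_trajectories

        write_trajectories(mimic.path_, out_dir / "trajectories.csv")
        _dump(report, out_dir / "report.json")
    return report


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def _dump(obj, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, allow_nan=True)
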