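"""End-to-end study pipeline: simulate -> qc -> fit -> bootstrap -> vpc ->
effects, with resumable stages and a machine-readable summary.

Every stage writes its outputs under the configured directory; a manifest
records the configuration fingerprint so that rerunning with unchanged
configuration skips completed stages and reproduces the same summary
byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .datamodel import (BatchDescriptor, PopulationParams, StudyDesign,
                        default_design)
from .dosing import dosing_linearity, dosing_precision
from .effects import ENDPOINTS, compare_groups, endpoint_summaries
from .estimation import FitResult, bootstrap, cwres, fit, vpc
from .io import read_dataset, records_to_frame, write_dataset
from .population import ModelConfig
from .simulate import (SimulationConfig, simulate_effects_study,
                       simulate_linearity_experiment, simulate_pk_study)

__all__ = ["PipelineConfig", "run_pipeline", "load_scenario"]

log = logging.getLogger("mozzipk")

STAGES = ("simulate", "qc", "fit", "bootstrap", "vpc", "effects")


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: Path = Path("mozzipk_out")
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    design: StudyDesign = field(default_factory=default_design)
    truth: PopulationParams = field(default_factory=PopulationParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_bootstrap: int = 200
    n_vpc: int = 200

    def fingerprint(self) -> str:
        payload = repr((self.seed, sorted(self.stages.items()),
                        dataclasses.asdict(self.design),
                        dataclasses.asdict(self.truth),
                        dataclasses.asdict(self.model),
                        self.n_bootstrap, self.n_vpc))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_scenario(path, outdir: Optional[Path] = None,
                  seed: Optional[int] = None) -> PipelineConfig:
    """Build a pipeline configuration from a YAML (or JSON) scenario file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cfg = PipelineConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if seed is not None:
        cfg.seed = int(seed)
    if outdir is not None:
        cfg.outdir = Path(outdir)
    elif "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    if "stages" in raw:
        cfg.stages.update({k: bool(v) for k, v in raw["stages"].items()})
    if "design" in raw:
        d = raw["design"]
        design = default_design()
        if "combos" in d:
            design.batches = [BatchDescriptor(batch_id=f"B{i + 1}",
                                              arms=("IVM", f"IVM_{c}"))
                              for i, c in enumerate(d["combos"])]
        for key in ("n_per_timepoint", "blood_conc_ug_ml", "lloq_ng"):
            if key in d:
                setattr(design, key, d[key])
        if "time_grid_h" in d:
            design.time_grid_h = tuple(float(t) for t in d["time_grid_h"])
        cfg.design = design
    if "truth" in raw:
        cfg.truth = PopulationParams(**raw["truth"])
    if "model" in raw:
        cfg.model = ModelConfig(**raw["model"])
    for key in ("n_bootstrap", "n_vpc"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    return cfg


def _manifest_path(cfg: PipelineConfig) -> Path:
    return cfg.outdir / "manifest.json"


def _load_manifest(cfg: PipelineConfig) -> dict:
    p = _manifest_path(cfg)
    if p.exists():
        m = json.loads(p.read_text())
        if m.get("fingerprint") == cfg.fingerprint():
            return m
    return {"fingerprint": cfg.fingerprint(), "completed": []}


def _save_manifest(cfg: PipelineConfig, manifest: dict) -> None:
    _manifest_path(cfg).write_text(json.dumps(manifest, sort_keys=True))


def _fit_to_json(result: FitResult) -> dict:
    return result.to_dict()


def _fit_from_json(payload: dict, model: ModelConfig) -> FitResult:
    return FitResult(
        estimates=PopulationParams(**payload["estimates"]),
        ofv=payload["ofv"], converged=payload["converged"],
        n_obs=payload["n_obs"], n_blq_dropped=payload["n_blq_dropped"],
        param_names=payload["param_names"], model_config=model,
        se=payload.get("se"), rse_percent=payload.get("rse_percent"),
        boundary=payload.get("boundary", []),
        message=payload.get("message", ""))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a summary JSON.

    Stage failures raise with the stage name; outputs of completed stages
    are retained.  Rerunning with an unchanged configuration skips stages
    whose outputs already exist.
    """
    cfg = config
    cfg.outdir = Path(cfg.outdir)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.outdir / "pipeline.log")
    log.addHandler(handler)
    manifest = _load_manifest(cfg)
    summary: dict = {"seed": cfg.seed, "fingerprint": cfg.fingerprint(),
                     "stages": {}}
    enabled = cfg.stages

    def done(stage):
        return stage in manifest["completed"]

    def mark(stage, t0):
        if stage not in manifest["completed"]:
            manifest["completed"].append(stage)
        _save_manifest(cfg, manifest)
        log.info("stage %s finished in %.2f s (seed %d)",
                 stage, time.perf_counter() - t0, cfg.seed)

    try:
        # ------------------------------------------------ simulate
        pk_path = cfg.outdir / "pk_dataset.csv"
        lin_path = cfg.outdir / "linearity.csv"
        eff_path = cfg.outdir / "effects.csv"
        if enabled.get("simulate"):
            t0 = time.perf_counter()
            if not (done("simulate") and pk_path.exists()):
                sim_cfg = SimulationConfig(design=cfg.design, truth=cfg.truth,
                                           model=cfg.model, seed=cfg.seed)
                write_dataset(simulate_pk_study(sim_cfg), pk_path)
                write_dataset(simulate_linearity_experiment(seed=cfg.seed),
                              lin_path)
                write_dataset(simulate_effects_study(seed=cfg.seed), eff_path)
            mark("simulate", t0)
            summary["stages"]["simulate"] = {
                "pk_records": int(len(pd.read_csv(pk_path)))}
        # ------------------------------------------------ qc
        if enabled.get("qc"):
            t0 = time.perf_counter()
            if not lin_path.exists():
                raise RuntimeError("qc stage requires the simulate stage "
                                   "(no linearity dataset found)")
            lin = read_dataset(lin_path, schema="linearity")
            qc_norm = dosing_precision(lin, normalize_by_weight=True)
            qc_raw = dosing_precision(lin, normalize_by_weight=False)
            slope, intercept, r2 = dosing_linearity(lin)
            qc_norm.per_concentration.to_csv(cfg.outdir / "dosing_summary.csv",
                                             index=False)
            summary["stages"]["qc"] = {
                "cv_percent_normalized": [round(v, 4) for v in
                                          qc_norm.per_concentration["cv_percent"]],
                "cv_percent_raw": [round(v, 4) for v in
                                   qc_raw.per_concentration["cv_percent"]],
                "slope_ul": round(slope, 6), "r_squared": round(r2, 6)}
            mark("qc", t0)
        # ------------------------------------------------ fit
        fit_path = cfg.outdir / "fit.json"
        fit_result = None
        if enabled.get("fit"):
            t0 = time.perf_counter()
            if done("fit") and fit_path.exists():
                fit_result = _fit_from_json(json.loads(fit_path.read_text()),
                                            cfg.model)
            else:
                if not pk_path.exists():
                    raise RuntimeError("fit stage requires the simulate stage "
                                       "(no PK dataset found)")
                data = pd.read_csv(pk_path)
                fit_result = fit(data, cfg.model)
                fit_path.write_text(json.dumps(_fit_to_json(fit_result),
                                               sort_keys=True))
                fit_result.parameter_table().to_csv(
                    cfg.outdir / "parameter_table.csv", index=False)
                cwres(fit_result, data).to_csv(cfg.outdir / "cwres.csv",
                                               index=False)
            mark("fit", t0)
            summary["stages"]["fit"] = _fit_to_json(fit_result)
        # ------------------------------------------------ bootstrap
        if enabled.get("bootstrap"):
            if fit_result is None:
                raise RuntimeError("bootstrap stage requires the fit stage")
            t0 = time.perf_counter()
            boot_path = cfg.outdir / "bootstrap.csv"
            summ_path = cfg.outdir / "bootstrap_summary.json"
            if done("bootstrap") and summ_path.exists():
                boot_summary = json.loads(summ_path.read_text())
            else:
                data = pd.read_csv(pk_path)
                boot = bootstrap(data, cfg.model, n=cfg.n_bootstrap,
                                 seed=cfg.seed, base_fit=fit_result)
                boot.samples.to_csv(boot_path, index=False)
                boot_summary = {"n_requested": boot.n_requested,
                                "n_failed": boot.n_failed,
                                "median": boot.median, "ci90": boot.ci90}
                summ_path.write_text(json.dumps(boot_summary, sort_keys=True))
                fit_result.parameter_table(boot).to_csv(
                    cfg.outdir / "parameter_table.csv", index=False)
            mark("bootstrap", t0)
            summary["stages"]["bootstrap"] = boot_summary
        # ------------------------------------------------ vpc
        if enabled.get("vpc"):
            if fit_result is None:
                raise RuntimeError("vpc stage requires the fit stage")
            t0 = time.perf_counter()
            vpc_path = cfg.outdir / "vpc.csv"
            if not (done("vpc") and vpc_path.exists()):
                data = pd.read_csv(pk_path) if pk_path.exists() else None
                res = vpc(fit_result, cfg.design, n_sim=cfg.n_vpc,
                          seed=cfg.seed, data=data)
                res.table.to_csv(vpc_path, index=False)
            vpc_table = pd.read_csv(vpc_path)
            summary["stages"]["vpc"] = {"n_simulations": cfg.n_vpc,
                                        "n_bins": int(len(vpc_table))}
            mark("vpc", t0)
        # ------------------------------------------------ effects
        if enabled.get("effects"):
            t0 = time.perf_counter()
            if not eff_path.exists():
                raise RuntimeError("effects stage requires the simulate stage "
                                   "(no effects dataset found)")
            recs = read_dataset(eff_path, schema="effects")
            endpoint_summaries(recs).to_csv(cfg.outdir / "effects_summary.csv",
                                            index=False)
            comp_rows = []
            effects_summary = {}
            for ep in ENDPOINTS:
                res = compare_groups(recs, ep)
                effects_summary[ep] = {"branch": res.branch,
                                       "omnibus_p": res.omnibus_p}
                pw = res.pairwise.copy()
                pw.insert(0, "endpoint", ep)
                comp_rows.append(pw)
            pd.concat(comp_rows).to_csv(cfg.outdir / "effects_comparisons.csv",
                                        index=False)
            summary["stages"]["effects"] = effects_summary
            mark("effects", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    (cfg.outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1))
    return summary
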