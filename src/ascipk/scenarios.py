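"""Configuration-driven scenario execution.

A scenario bundles compounds, a trial design, mechanism flags and a seed,
and produces a reproducible output bundle (profiles, PK summary, ratio
tables, manifest).  Scenarios are plain dictionaries (or YAML files) so a
study can be re-run from its manifest; all randomness flows through the
design seed.  These functions are the package's entry points — see the
``examples/`` scripts for narrative usage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .compounds import load_compound
from .engine import Calibration, EngineOptions, calibrate
from .population import PopulationSpec
from .trials import Regimen, TrialDesign, oi_study, run_trial, summarize_metrics, trial_ratios

log = logging.getLogger("ascipk")


@dataclass
class ScenarioConfig:
    scenario_id: str
    victim: str                       # compound name or path
    victim_regimen: dict = field(default_factory=dict)
    perpetrator: Optional[str] = None
    perpetrator_regimen: Optional[dict] = None
    probe_mode: bool = False          # victim is a reduced probe; perpetrator mechanistic
    impairment: Optional[str] = None  # organ-impairment study instead of DDI
    population: dict = field(default_factory=dict)
    n_trials: int = 10
    n_subjects: int = 10
    seed: int = 2024
    victim_offset_h: float = 0.0
    bcrp_enabled: bool = True
    ehc_fraction: float = 0.0
    inhibition_enabled: bool = True
    induction_enabled: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_scenario(config: ScenarioConfig, out_dir: str | Path | None = None,
                 calibration: Calibration | None = None) -> dict:
    """Execute one scenario and (optionally) write its output bundle.

    Returns a dict with the PK summary, ratio results where applicable, and
    a manifest carrying the seed, package version and config hash; re-running
    the same config reproduces the outputs exactly.
    """
    # resolve references before any simulation starts
    victim = load_compound(config.victim)
    perpetrator = load_compound(config.perpetrator) if config.perpetrator else None
    options = EngineOptions(bcrp_enabled=config.bcrp_enabled,
                            ehc_fraction=config.ehc_fraction,
                            inhibition_enabled=config.inhibition_enabled,
                            induction_enabled=config.induction_enabled)
    if calibration is None:
        mechanistic = perpetrator if config.probe_mode else victim
        if mechanistic.reduced_pk is None:
            log.info("calibrating clearance scalars for %s", mechanistic.name)
            calibration = calibrate(mechanistic)
        else:
            calibration = Calibration()

    manifest = {"scenario_id": config.scenario_id, "seed": config.seed,
                "version": __version__, "config_hash": config.config_hash()}
    result: dict = {"manifest": manifest}

    if config.impairment:
        ratios = oi_study(config.impairment, config.victim_regimen["dose"],
                          victim, calibration=calibration,
                          n_subjects=config.n_subjects, seed=config.seed,
                          options=options)
        result["ratios"] = {k: {"gmr": r.geometric_mean_ratio, "ci90": r.ci90}
                            for k, r in ratios.items()}
    else:
        design = TrialDesign(
            victim=Regimen(**config.victim_regimen),
            perpetrator=(Regimen(**config.perpetrator_regimen)
                         if config.perpetrator_regimen else None),
            population=PopulationSpec(**config.population),
            n_trials=config.n_trials, n_subjects=config.n_subjects,
            seed=config.seed, victim_offset_h=config.victim_offset_h)
        df = run_trial(design, victim, perpetrator, calibration=calibration,
                       options=options, probe_mode=config.probe_mode)
        result["metrics"] = df
        result["summary"] = {
            arm: summarize_metrics(
                [row for row in df[df.arm == arm].itertuples()])
            for arm in df.arm.unique()}
        if perpetrator is not None:
            result["ratios"] = {}
            for metric in ("auc_inf", "cmax"):
                r = trial_ratios(df, metric)
                result["ratios"][metric] = {"gmr": r.geometric_mean_ratio,
                                            "ci90": r.ci90}

    if out_dir is not None:
        out = Path(out_dir) / config.scenario_id
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        if "metrics" in result:
            result["metrics"].to_csv(out / "pk_metrics.csv", index=False)
        if "ratios" in result:
            with open(out / "ratios.json", "w") as fh:
                json.dump(result["ratios"], fh, indent=2)
    return result


def run_suite(configs: list[ScenarioConfig], out_dir: str | Path | None = None,
              calibration: Calibration | None = None) -> pd.DataFrame:
    """Run a list of scenarios; failures are isolated per scenario.

    Returns a consolidated (forest-plot ready) ratio table; an empty list
    yields an empty table.
    """
    rows = []
    for cfg in configs:
        try:
            res = run_scenario(cfg, out_dir=out_dir, calibration=calibration)
        except Exception as exc:  # noqa: BLE001 - isolate scenario failures
            log.error("scenario %s failed: %s", cfg.scenario_id, exc)
            rows.append({"scenario_id": cfg.scenario_id, "status": "failed",
                         "error": str(exc)})
            continue
        ratios = res.get("ratios", {})
        if ratios:
            for metric, r in ratios.items():
                rows.append({"scenario_id": cfg.scenario_id, "status": "ok",
                             "metric": metric, "gmr": r["gmr"],
                             "ci90_low": r["ci90"][0], "ci90_high": r["ci90"][1]})
        else:
            rows.append({"scenario_id": cfg.scenario_id, "status": "ok"})
    columns = ["scenario_id", "status", "metric", "gmr", "ci90_low",
               "ci90_high", "error"]
    df = pd.DataFrame(rows)
    return df.reindex(columns=[c for c in columns if df.empty or c in df.columns])


def verification_suite(n_trials: int = 2, n_subjects: int = 5,
                       seed: int = 2024) -> list[ScenarioConfig]:
    """The clinical verification scenarios (victim DDI, perpetrator DDI and
    organ impairment at the 40 mg dose level)."""
    mk = ScenarioConfig
    return [
        mk("clarithromycin_40mg", victim="asciminib",
           victim_regimen={"dose": 40, "interval": "single", "start_day": 5},
           perpetrator="clarithromycin",
           perpetrator_regimen={"dose": 500, "interval": "BID", "n_days": 8},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("itraconazole_40mg", victim="asciminib",
           victim_regimen={"dose": 40, "interval": "single", "start_day": 5},
           perpetrator="itraconazole",
           perpetrator_regimen={"dose": 200, "interval": "QD", "n_days": 8},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("rifampicin_40mg", victim="asciminib",
           victim_regimen={"dose": 40, "interval": "single", "start_day": 5},
           perpetrator="rifampicin",
           perpetrator_regimen={"dose": 600, "interval": "QD", "n_days": 6},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("imatinib_40mg", victim="asciminib",
           victim_regimen={"dose": 40, "interval": "single", "start_day": 5},
           perpetrator="imatinib",
           perpetrator_regimen={"dose": 400, "interval": "QD", "n_days": 8},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("midazolam_asciminib_40bid", victim="midazolam", probe_mode=True,
           victim_regimen={"dose": 4, "interval": "single", "start_day": 3},
           perpetrator="asciminib",
           perpetrator_regimen={"dose": 40, "interval": "BID", "n_days": 5},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("swarfarin_asciminib_40bid", victim="swarfarin", probe_mode=True,
           victim_regimen={"dose": 2.5, "interval": "single", "start_day": 3},
           perpetrator="asciminib",
           perpetrator_regimen={"dose": 40, "interval": "BID", "n_days": 8},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("repaglinide_asciminib_40bid", victim="repaglinide", probe_mode=True,
           victim_regimen={"dose": 0.5, "interval": "single", "start_day": 3},
           perpetrator="asciminib",
           perpetrator_regimen={"dose": 40, "interval": "BID", "n_days": 3},
           n_trials=n_trials, n_subjects=n_subjects, seed=seed),
        mk("mild_hi_40mg", victim="asciminib", impairment="CP-A",
           victim_regimen={"dose": 40, "interval": "single"},
           n_subjects=n_subjects, seed=seed),
        mk("moderate_hi_40mg", victim="asciminib", impairment="CP-B",
           victim_regimen={"dose": 40, "interval": "single"},
           n_subjects=n_subjects, seed=seed),
        mk("severe_hi_40mg", victim="asciminib", impairment="CP-C-ugt-modified",
           victim_regimen={"dose": 40, "interval": "single"},
           n_subjects=n_subjects, seed=seed),
        mk("severe_ri_40mg", victim="asciminib", impairment="RI-severe",
           victim_regimen={"dose": 40, "interval": "single"},
           n_subjects=n_subjects, seed=seed),
    ]
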