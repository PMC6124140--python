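"""Scenario configuration files, run manifests and tabular output writers.

Scenario files are YAML or JSON with the blocks::

    web: path/to/web.json
    stocking: {whitefish: 200.0, perch: 0.0}   # or per-year lists
    harvest: {F_max: 0.00549, S: [0, 0, 0.3333, 0.6667, 1.0], fishing_start_year: 100}
    years_unfished: 100
    years_fished: 100
    season_length: 90
    record_days: [45, 90]
    solver: {method: LSODA, rtol: 1.0e-8, atol: 1.0e-10}

All outputs are tidy long-format CSV so downstream tools consume them directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .harvest import HarvestPolicy, DEFAULT_SELECTIVITY
from .life_history import StockingPlan
from .simulate import ScenarioConfig, ScenarioResult, SolverSettings

__all__ = ["load_scenario", "scenario_to_dict", "config_hash", "run_manifest", "write_result"]


def _load_doc(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_scenario(path: str | Path) -> tuple[str | None, ScenarioConfig]:
    """Read a scenario file; returns (web path or None, ScenarioConfig)."""
    doc = _load_doc(path)
    if not isinstance(doc, dict):
        raise ValueError(f"scenario file {path} is not a mapping")
    harvest = None
    if "harvest" in doc and doc["harvest"] is not None:
        h = dict(doc["harvest"])
        h.pop("fishing_start_year", None)  # implied by years_unfished
        harvest = HarvestPolicy(F_max=float(h.get("F_max", 0.5 / 91)),
                                S=tuple(h.get("S", DEFAULT_SELECTIVITY)))
    solver = SolverSettings(**doc.get("solver", {}))
    cfg = ScenarioConfig(
        stocking=StockingPlan(dict(doc.get("stocking", {}))),
        harvest=harvest,
        years_unfished=int(doc.get("years_unfished", 100)),
        years_fished=int(doc.get("years_fished", 100)),
        season_length=float(doc.get("season_length", 90.0)),
        record_days=tuple(float(d) for d in doc.get("record_days", (45.0, 90.0))),
        solver=solver,
    )
    return doc.get("web"), cfg


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    d = {
        "stocking": cfg.stocking.densities,
        "harvest": None if cfg.harvest is None else {"F_max": cfg.harvest.F_max, "S": list(cfg.harvest.S)},
        "years_unfished": cfg.years_unfished,
        "years_fished": cfg.years_fished,
        "season_length": cfg.season_length,
        "record_days": list(cfg.record_days),
        "solver": asdict(cfg.solver),
    }
    if cfg.initial_state is not None:
        d["initial_state"] = [float(v) for v in cfg.initial_state]
    return d


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable hash of everything that determines a run (model is deterministic)."""
    blob = json.dumps(scenario_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_manifest(result: ScenarioResult, web_path: str | None = None) -> dict:
    """Reproducibility record: config echo, web provenance, solver statistics."""
    return {
        "config": scenario_to_dict(result.config),
        "config_hash": config_hash(result.config),
        "web": web_path,
        "n_guilds": result.web.n_guilds,
        "n_links": len(result.web.links),
        "years": result.years,
        "rhs_evaluations": int(result.nfev),
    }


def write_result(result: ScenarioResult, outdir: str | Path, web_path: str | None = None) -> None:
    """Write biomass.csv, catches.csv and manifest.json under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "biomass.csv", index=False)
    result.catches_to_frame().to_csv(out / "catches.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(run_manifest(result, web_path), indent=1))
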