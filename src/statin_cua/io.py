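"""Run configuration, result serialization and provenance sidecars."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .frontier import (STATUS_DOMINATED, STATUS_EXTENDED, STATUS_FRONTIER,
                       STATUS_REFERENCE, FrontierResult, PairVerdict)
from .params import (RMB_PER_USD, TABLE1, WTP_BASE, WTP_UPPER,
                     default_parameters, validate_parameters)
from .strategy import THRESHOLD_GRID, StrategyOutcome

log = logging.getLogger("statin_cua")

_STATUS_LABEL = {
    STATUS_REFERENCE: "Ref",
    STATUS_FRONTIER: "frontier",
    STATUS_DOMINATED: "Dominated",
    STATUS_EXTENDED: "Extended dominance",
}


class ConfigError(ValueError):
    """A run configuration is incomplete or out of range."""


@dataclass
class RunConfig:
    """Validated inputs of one analysis run."""

    parameters: dict[str, float]
    model: str = "soft"
    thresholds: list[float] = field(default_factory=list)
    wtp: list[float] = field(default_factory=lambda: [WTP_BASE, WTP_UPPER])
    n_psa: int = 1000
    seed: int = 0
    transitions: str | None = None
    cohort: str | None = None
    weights: str | None = None
    output_dir: str = "."
    allow_discount_override: bool = False


def default_config() -> dict:
    """A complete config mapping with base-case values everywhere."""
    return {
        "parameters": default_parameters(),
        "model": "soft",
        "thresholds": list(THRESHOLD_GRID["soft"]),
        "wtp": [WTP_BASE, WTP_UPPER],
        "n_psa": 1000,
        "seed": 0,
    }


def load_and_validate_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration and validate it.

    Checks parameter-manifest completeness (every model parameter must be
    present), value ranges (discount rate within the 0-8% sensitivity range
    unless explicitly overridden), threshold-grid membership, and the
    existence of referenced files.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} did not parse to a mapping")
    params = raw.get("parameters")
    if not isinstance(params, dict):
        raise ConfigError("config must contain a 'parameters' mapping")
    missing = validate_parameters(params)
    if missing:
        raise ConfigError(f"config missing parameters: {', '.join(missing)}")
    unknown = sorted(set(params) - set(TABLE1))
    if unknown:
        warnings.warn(f"config has unknown parameters (ignored): {unknown}")

    cfg = RunConfig(
        parameters={k: float(params[k]) for k in TABLE1},
        model=raw.get("model", "soft"),
        thresholds=[float(t) for t in raw.get("thresholds", [])],
        wtp=[float(w) for w in raw.get("wtp", [WTP_BASE, WTP_UPPER])],
        n_psa=int(raw.get("n_psa", 1000)),
        seed=int(raw.get("seed", 0)),
        transitions=raw.get("transitions"),
        cohort=raw.get("cohort"),
        weights=raw.get("weights"),
        output_dir=raw.get("output_dir", "."),
        allow_discount_override=bool(raw.get("allow_discount_override",
                                             False)),
    )
    if cfg.model not in THRESHOLD_GRID:
        raise ConfigError(f"unknown risk model {cfg.model!r}")
    rate = cfg.parameters["discount_rate"]
    if not cfg.allow_discount_override and not 0 <= rate <= 0.08:
        raise ConfigError(
            f"discount_rate {rate} outside the sensitivity range [0, 0.08]; "
            f"set allow_discount_override to use it anyway")
    grid = THRESHOLD_GRID[cfg.model]
    off_grid = [t for t in cfg.thresholds if t not in grid]
    if off_grid:
        raise ConfigError(
            f"thresholds {off_grid} outside the {cfg.model}-model grid "
            f"{sorted(grid)}")
    for label in ("transitions", "cohort", "weights"):
        p = getattr(cfg, label)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{label} file not found: {p}")
    log.info("config %s validated: model=%s, %d thresholds",
             path, cfg.model, len(cfg.thresholds))
    return cfg


# ---------------------------------------------------------------------------
# result frames
# ---------------------------------------------------------------------------

def outcomes_to_frame(outcomes: list[StrategyOutcome],
                      rmb: bool = False) -> pd.DataFrame:
    """Strategy outcomes as a ladder table (cost/QALY columns)."""
    rows = []
    for o in outcomes:
        row = {
            "strategy": o.label,
            "model": o.strategy.model,
            "threshold_pct": o.strategy.threshold,
            "statin_eligible_pct": round(o.eligible_pct, 1),
            "ascvd_events_pct": None if o.events_pct is None
            else round(o.events_pct, 2),
            "cost_usd": round(o.cost, 2),
            "qalys": round(o.qalys, 4),
        }
        if rmb:
            row["cost_rmb"] = round(o.cost * RMB_PER_USD, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def frontier_to_frame(result: FrontierResult, rmb: bool = False
                      ) -> pd.DataFrame:
    """Frontier classification with a status column and final ICERs."""
    rows = []
    for e in result.entries:
        o = e.outcome
        row = {
            "strategy": o.label,
            "model": o.strategy.model,
            "threshold_pct": o.strategy.threshold,
            "statin_eligible_pct": round(o.eligible_pct, 1),
            "cost_usd": round(o.cost, 2),
            "qalys": round(o.qalys, 4),
            "status": _STATUS_LABEL[e.status],
            "icer_usd_per_qaly": None if e.icer is None else round(e.icer, 2),
        }
        if rmb:
            row["cost_rmb"] = round(o.cost * RMB_PER_USD, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_to_frame(verdicts: list[PairVerdict]) -> pd.DataFrame:
    """Matched-proportion soft-vs-hard verdicts as a table."""
    rows = []
    for v in verdicts:
        rows.append({
            "soft_strategy": v.soft.label,
            "soft_eligible_pct": round(v.soft.eligible_pct, 1),
            "hard_strategy": v.hard.label,
            "hard_eligible_pct": round(v.hard.eligible_pct, 1),
            "soft_cost_usd": round(v.soft.cost, 2),
            "hard_cost_usd": round(v.hard.cost, 2),
            "soft_qalys": round(v.soft.qalys, 4),
            "hard_qalys": round(v.hard.qalys, 4),
            "verdict": v.verdict,
            "icer_usd_per_qaly": None if v.icer is None else round(v.icer, 2),
        })
    return pd.DataFrame(rows)


def write_results(frame: pd.DataFrame, path, *, seed: int | None = None,
                  config: dict | None = None) -> Path:
    """Write a result table with a JSON provenance sidecar.

    The sidecar records the package version, seed, a hash of the effective
    configuration and the creation time, so any output file can be traced
    back to a reproducible run.  Returns the sidecar path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if frame.empty:
        warnings.warn(f"writing header-only result file {path}")
    frame.to_csv(path, index=False)
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({
        "package": "statin_cua",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "rows": int(len(frame)),
    }, indent=2, default=str))
    return sidecar
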