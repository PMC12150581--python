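"""Pipeline orchestration and report generation.

Wires the stages together — load or simulate a panel, apply selection and
inclusion rules where requested, estimate, attach uncertainty — and emits a
report bundle of tidy tables: headline estimates with intervals, the
event-study path, group-year mean trajectories, group-period observed and
counterfactual probabilities, and per-indicator prevented events.  Every
table carries the config hash and seed that produced it; rounding is
applied only in the human-readable summary, never in the exported machine
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .estimator import att_summary, estimate
from .panel import PanelDataset, load_panel, write_panel
from .simulate import DgpConfig, generate_panel
from .uncertainty import BootstrapConfig, BootstrapResult, parametric_bootstrap

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "pretrend_diagnostic",
]

logger = logging.getLogger(__name__)

#: decimal places for the human-readable summary (negative = power of ten);
#: effect measures to two decimals, prevented events to the nearest hundred
DEFAULT_ROUNDING = {"delta": 2, "odds_ratio": 2, "risk_ratio": 2, "prevented": -2}


@dataclass
class PipelineConfig:
    """Full pipeline configuration; exactly one data source must be set."""

    panel_path: str | None = None
    metadata_path: str | None = None
    simulate: DgpConfig | None = None
    onset_year: int = 2017
    reference_year: int = 2016
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    output_dir: str | None = None
    rounding: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))

    def __post_init__(self) -> None:
        if (self.panel_path is None) == (self.simulate is None):
            raise ValueError(
                "configure exactly one data source: input paths or a simulate block"
            )

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        inp = raw.pop("input", {}) or {}
        boot = raw.pop("bootstrap", {}) or {}
        if sim is not None:
            if "effect_path" in sim:
                sim["effect_path"] = {int(k): float(v)
                                      for k, v in sim["effect_path"].items()}
            if "years" in sim:
                sim["years"] = tuple(int(y) for y in sim["years"])
            sim = DgpConfig(**sim)
        return cls(
            panel_path=inp.get("panel"),
            metadata_path=inp.get("metadata"),
            simulate=sim,
            bootstrap=BootstrapConfig(**boot),
            **raw,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"]["years"] = list(self.simulate.years)
            d["simulate"]["effect_path"] = {
                int(k): float(v) for k, v in self.simulate.effect_path.items()
            }
        return d

    def hash(self) -> str:
        # analytic configuration only: where the report lands must not
        # change what it contains
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


@dataclass
class ReportBundle:
    """All pipeline outputs plus provenance (config hash, seed, warnings)."""

    config: PipelineConfig
    panel: PanelDataset
    estimates: pd.DataFrame
    event_study: pd.DataFrame
    group_year_means: pd.DataFrame
    group_period_probabilities: pd.DataFrame
    prevented_by_indicator: pd.DataFrame
    summary: dict[str, Any]
    bootstrap: BootstrapResult | None = None

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(self.panel, out / "panel.csv")
        for name in ("estimates", "event_study", "group_year_means",
                     "group_period_probabilities", "prevented_by_indicator"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)
        with open(out / "run.log", "w") as fh:
            fh.write(f"config_hash: {self.summary['config_hash']}\n")
            fh.write(f"seed: {self.summary['seed']}\n")
            for msg in self.summary["warnings"]:
                fh.write(f"WARNING: {msg}\n")
        if self.bootstrap is not None:
            self.bootstrap.draws_frame().to_csv(out / "bootstrap_draws.csv",
                                                index=False)
        return out


def _round_to(x: float, digits: int) -> float:
    return float(np.round(x, digits))


def run_pipeline(config: PipelineConfig, *, with_bootstrap: bool = True
                 ) -> ReportBundle:
    """Execute load/simulate → estimate → uncertainty → report tables."""
    counter = _WarningCounter()
    root = logging.getLogger("qualdid")
    root.addHandler(counter)
    try:
        if config.simulate is not None:
            logger.info("simulating panel (seed=%s)", config.simulate.seed)
            panel = generate_panel(config.simulate)
        else:
            logger.info("loading panel from %s", config.panel_path)
            panel = load_panel(
                config.panel_path, config.metadata_path,
                program_onset_year=config.onset_year,
                reference_year=config.reference_year,
            )
        logger.info("estimating on %d indicators × %d years",
                    len(panel.metas), len(panel.years))
        est = estimate(panel)
        att = att_summary(panel, est.delta)

        boot = None
        if with_bootstrap and config.bootstrap.n_replicates > 0:
            logger.info("parametric bootstrap, %d replicates",
                        config.bootstrap.n_replicates)
            boot = parametric_bootstrap(panel, config.bootstrap)
    finally:
        root.removeHandler(counter)

    from .estimator import group_year_means as gym

    means = gym(panel)
    if boot is not None:
        estimates = boot.intervals()
        es = boot.event_study_intervals()
    else:
        estimates = pd.DataFrame({
            "quantity": ["delta", "odds_ratio", "risk_ratio", "p_obs", "p_cf",
                         "prevented_total"],
            "estimate": [est.delta, est.odds_ratio, att.risk_ratio, att.p_obs,
                         att.p_cf, att.prevented_total],
            "ci_low": np.nan, "ci_high": np.nan,
        })
        es = pd.DataFrame({
            "year": list(est.event_study),
            "delta_t": list(est.event_study.values()),
            "ci_low": np.nan, "ci_high": np.nan,
        })

    df = panel.to_frame()
    gp = (
        df.groupby(["group", "period"])
        .apply(lambda s: s.event_count.sum() / s.population_size.sum(),
               include_groups=False)
        .rename("p_observed").reset_index()
    )
    gp["p_counterfactual"] = np.where(
        (gp.group == "program") & (gp.period == "post"), att.p_cf, np.nan
    )
    prevented = pd.DataFrame(
        sorted(att.prevented_by_indicator.items()),
        columns=["indicator_id", "prevented_events"],
    )

    seed = (config.simulate.seed if config.simulate is not None else None)
    r = config.rounding
    summary = {
        "config_hash": config.hash(),
        "seed": seed,
        "bootstrap_seed": config.bootstrap.seed,
        "n_indicators": len(panel.metas),
        "n_cells": len(panel.cells),
        "delta": est.delta,
        "odds_ratio": est.odds_ratio,
        "risk_ratio": att.risk_ratio,
        "p_obs": att.p_obs,
        "p_cf": att.p_cf,
        "prevented_total": att.prevented_total,
        "rounded": {
            "delta": _round_to(est.delta, r.get("delta", 2)),
            "odds_ratio": _round_to(est.odds_ratio, r.get("odds_ratio", 2)),
            "risk_ratio": _round_to(att.risk_ratio, r.get("risk_ratio", 2)),
            "prevented_total": _round_to(att.prevented_total,
                                         r.get("prevented", -2)),
        },
        "warnings": counter.messages,
    }
    if boot is not None:
        for q in ("delta", "odds_ratio", "risk_ratio", "prevented_total"):
            summary[f"{q}_ci"] = list(boot.interval(q))

    hash_, seed_ = summary["config_hash"], summary["seed"]
    for tbl in (estimates, es, means, gp, prevented):
        tbl["config_hash"] = hash_
        tbl["seed"] = seed_

    bundle = ReportBundle(
        config=config, panel=panel, estimates=estimates, event_study=es,
        group_year_means=means, group_period_probabilities=gp,
        prevented_by_indicator=prevented, summary=summary, bootstrap=boot,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def pretrend_diagnostic(event_study: pd.DataFrame, pre_years,
                        reference_year: int | None = None) -> pd.DataFrame:
    """Flag pre-onset years whose event-study interval excludes zero.

    Under parallel trends all pre-onset δ_t should be statistically
    indistinguishable from zero; a flagged pre-year is evidence against the
    identifying assumption.  The reference year (δ ≡ 0 by construction) is
    never flagged.
    """
    pre_years = set(int(y) for y in pre_years)
    out = event_study[event_study.year.isin(pre_years)].copy()
    out["flagged"] = (out.ci_low > 0) | (out.ci_high < 0)
    if reference_year is not None:
        out.loc[out.year == reference_year, "flagged"] = False
    out["flagged"] = out["flagged"].fillna(False)
    if out.flagged.any():
        years = sorted(out.year[out.flagged])
        logger.warning("pre-trend diagnostic flagged year(s) %s", years)
    return out.reset_index(drop=True)
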