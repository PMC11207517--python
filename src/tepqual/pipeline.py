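"""End-to-end run orchestration: climate -> TEP -> fits -> weights -> TOPSIS.

A :class:`RunConfig` fully determines a run; the resulting
:class:`RunReport` contains only values recomputable from config + inputs,
plus a provenance hash of the config so reruns can be matched to their
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import mcdm, models, quality, synthetic
from .exceptions import PipelineStageError, TepqualError

logger = logging.getLogger(__name__)

_SINGLE_INDEX_FORMS = {"ssc": "log", "oac": "linear", "ssc_oac": "log"}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    climate_csv: str | None = None
    climate_scenario: dict | None = None
    par_unit: str = "w_m2"
    cardinals: tuple = (15.0, 22.0, 28.0, 35.0)
    origin_date: date | None = None
    quality: str = "table5"          # fixture name, CSV path, or "synthetic"
    quality_scenario: dict | None = None
    comprehensive: str = "table9"    # fixture name or "computed"
    factor_weights: dict | None = None
    directions: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineStageError("config", f"unknown keys: {sorted(unknown)}")
        if isinstance(raw.get("origin_date"), str):
            raw["origin_date"] = date.fromisoformat(raw["origin_date"])
        if isinstance(raw.get("cardinals"), list):
            raw["cardinals"] = tuple(raw["cardinals"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cardinals"] = list(self.cardinals)
        if self.origin_date is not None:
            out["origin_date"] = self.origin_date.isoformat()
        return out

    @property
    def provenance_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All numbers computed by a run, serializable to JSON."""

    provenance: dict
    tep_summary: dict | None
    correlations: dict
    fits: dict
    weights: dict
    topsis: dict
    comprehensive_fit: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def summary(self) -> str:
        lines = ["run " + self.provenance["config_hash"]]
        if self.tep_summary:
            lines.append(
                f"  TEP: {self.tep_summary['n_days']} days, "
                f"final {self.tep_summary['final_tep_mj_m2']:.2f} MJ/m2"
            )
        lines.append("  correlations vs TEP: " + ", ".join(
            f"{k}={v:.3f}" for k, v in self.correlations.items()))
        for name, fit in self.fits.items():
            lines.append(
                f"  {name} ({fit['form']}): R2={fit['r_squared']:.3f} RMSE={fit['rmse']:.3f}"
            )
        comp = self.comprehensive_fit
        lines.append(
            f"  comprehensive (logistic): R2={comp['r_squared']:.3f} RMSE={comp['rmse']:.3f}"
        )
        best = max(self.topsis["closeness"], key=self.topsis["closeness"].get)
        lines.append(f"  best option by TOPSIS: {best}")
        return "\n".join(lines)


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except (TepqualError, OSError, KeyError) as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapper
    return decorate


@_stage("climate")
def _run_climate(config: RunConfig):
    if config.climate_csv is None and config.climate_scenario is None:
        return None, None
    if config.climate_csv is not None:
        frame = climate_mod.read_climate_csv(config.climate_csv, par_unit=config.par_unit)
    else:
        scenario = synthetic.ClimateScenario(**_coerce_dates(config.climate_scenario))
        frame = synthetic.generate_climate(scenario)
    accumulator = climate_mod.TepAccumulator(
        cardinals=config.cardinals, origin_date=config.origin_date,
        par_unit="w_m2",  # read_climate_csv already converted
    )
    series = accumulator.accumulate(frame)
    logger.info("climate stage: %d hourly records -> %d days", len(frame), len(series))
    summary = {
        "n_days": len(series),
        "origin_date": str(series.origin_date),
        "final_tep_mj_m2": series.final,
    }
    return series, summary


def _coerce_dates(raw: dict) -> dict:
    out = dict(raw)
    for key in ("start", "end"):
        if isinstance(out.get(key), str):
            out[key] = date.fromisoformat(out[key])
    return out


@_stage("quality")
def _run_quality(config: RunConfig):
    if config.quality == "synthetic":
        scenario = synthetic.QualityScenario(**(config.quality_scenario or {}), seed=config.seed) \
            if "seed" not in (config.quality_scenario or {}) \
            else synthetic.QualityScenario(**config.quality_scenario)
        return synthetic.generate_quality(scenario), scenario
    if config.quality in ("table2", "table5"):
        return quality.load_fixture_table(config.quality), None
    return quality.validate_quality_csv(config.quality), None


@_stage("models")
def _run_fits(records, seed: int):
    frame = quality.records_to_frame(records)
    correlations = models.correlation_table(frame)
    tep = frame["tep"].to_numpy()
    fits = {}
    for index, form in _SINGLE_INDEX_FORMS.items():
        fitted = models.fit_curve(form, tep, frame[index].to_numpy(), random_state=seed)
        fits[index] = fitted.to_dict()
    return correlations, fits


@_stage("evaluation")
def _run_mcdm(records, config: RunConfig):
    frame = quality.records_to_frame(records)
    scorer = mcdm.ComprehensiveQualityScorer(
        factor_weights=config.factor_weights, directions=config.directions
    )
    scorer.fit(frame)
    scores = scorer.score_frame(frame)
    weights = {
        "entropy": dict(zip(scorer.entropy_weights_.labels,
                            map(float, scorer.entropy_weights_.weights))),
        "combined": dict(zip(scorer.combined_weights_.labels,
                             map(float, scorer.combined_weights_.weights))),
        "factors": dict(mcdm.DEFAULT_FACTOR_WEIGHTS if config.factor_weights is None
                        else config.factor_weights),
    }
    return scores, weights


@_stage("comprehensive")
def _run_comprehensive(records, scores: pd.DataFrame, config: RunConfig):
    frame = quality.records_to_frame(records)
    tep = frame["tep"].to_numpy()
    if config.comprehensive == "table9":
        tep, values = quality.paired_comprehensive_data()
    elif config.comprehensive == "computed":
        values = scores["closeness"].to_numpy()
    else:
        raise PipelineStageError("comprehensive", f"unknown source {config.comprehensive!r}")
    return models.fit_comprehensive_model(tep, values, random_state=config.seed).to_dict()


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute all stages and optionally write the report files to ``out_dir``."""
    series, tep_summary = _run_climate(config)
    records, _ = _run_quality(config)
    correlations, fits = _run_fits(records, config.seed)
    scores, weights = _run_mcdm(records, config)
    comp_fit = _run_comprehensive(records, scores, config)

    report = RunReport(
        provenance={"config_hash": config.provenance_hash, "seed": config.seed,
                    "config": config.to_dict()},
        tep_summary=tep_summary,
        correlations={k: float(v) for k, v in correlations.items()},
        fits=fits,
        weights=weights,
        topsis={
            "closeness": {k: float(v) for k, v in scores["closeness"].items()},
            "rank": {k: int(v) for k, v in scores["rank"].items()},
        },
        comprehensive_fit=comp_fit,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(indent=2) + "\n")
        scores.to_csv(out / "topsis.csv")
        pd.Series(report.correlations, name="r").to_csv(out / "correlations.csv")
        if series is not None:
            series.write_csv(out / "tep.csv")
    return report
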