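"""Three-stage analysis orchestration and machine-readable reporting.

``run_full_analysis`` executes, from one YAML config:

1. mean-changepoint detection (PELT, AIC penalty, 10-year minimum segment)
   on SSB, recruitment and productivity;
2. structural-break estimation on the six configured bivariate
   relationships;
3. the stochastic cusp fit with state classification, the linear/logistic
   alternatives and the four-criterion validation.

Outputs: one JSON report plus per-stage CSV tables.  Given the same config
and seed the JSON report is bit-identical apart from its timestamp.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breakpoint import BreakpointFit, fit_relationships
from .changepoint import Segmentation, aic_penalty, pelt_mean
from .cusp import (
    CuspFit,
    CuspValidationReport,
    fit_alternatives,
    fit_cusp,
    predict_states,
    validate_cusp,
)
from .data_model import (
    AnalysisConfig,
    ReferenceLevels,
    StockSeriesTable,
    ValidationError,
    read_stock_csv,
    resolve_variable,
)
from .synthetic_data import make_tipping_fixture

_FIXTURES = {"tipping": make_tipping_fixture}


@dataclass(frozen=True)
class AnalysisReport:
    """Bundle of all stage results plus provenance."""

    table: StockSeriesTable
    segmentations: tuple[Segmentation, ...]
    relationship_fits: tuple[BreakpointFit, ...]
    cusp_fit: CuspFit
    validation: CuspValidationReport
    predicted_state: np.ndarray
    config: AnalysisConfig
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "segmentations": [s.to_dict() for s in self.segmentations],
            "relationships": [f.to_dict() for f in self.relationship_fits],
            "cusp": self.cusp_fit.to_dict(),
            "validation": self.validation.to_dict(),
            "predicted_state": [float(v) for v in self.predicted_state],
            "regime_summary": summarize_regimes(self).to_dict(orient="list"),
        }


def load_config(path: str | Path) -> tuple[dict, AnalysisConfig]:
    """Parse and schema-check a YAML pipeline config (validation-first)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValidationError("config must be a YAML mapping")
    known = {"input", "seed", "changepoint", "breakpoint", "cusp",
             "reference_levels"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config section(s): {sorted(unknown)}")
    inp = raw.get("input") or {}
    if not ("csv" in inp) ^ ("fixture" in inp):
        raise ValidationError("config input must name exactly one of csv/fixture")
    if "fixture" in inp and inp["fixture"] not in _FIXTURES:
        raise ValidationError(
            f"unknown fixture {inp['fixture']!r}; available: {sorted(_FIXTURES)}")

    cp = raw.get("changepoint") or {}
    bp = raw.get("breakpoint") or {}
    cu = raw.get("cusp") or {}
    ref = raw.get("reference_levels")
    cfg = AnalysisConfig(
        min_segment_length=int(cp.get("min_segment_length", 10)),
        penalty_kind=str(cp.get("penalty", "aic")),
        max_breaks=int(bp.get("max_breaks", 5)),
        min_break_fraction=float(bp.get("min_break_fraction", 0.15)),
        seed=int(raw.get("seed", 0)),
        relationships=tuple(
            tuple(pair) for pair in bp.get(
                "relationships", AnalysisConfig().relationships)
        ),
        changepoint_series=tuple(
            cp.get("series", AnalysisConfig().changepoint_series)),
        state_var=cu.get("state", "ssb"),
        asym_var=cu.get("asymmetry", "scaled_pressure"),
        bifur_var=cu.get("bifurcation", "sst"),
        reference_levels=None if ref is None else ReferenceLevels(**ref),
    )
    return dict(raw), cfg


def _load_table(raw: Mapping[str, Any], cfg: AnalysisConfig) -> StockSeriesTable:
    inp = raw.get("input") or {}
    if "csv" in inp:
        return read_stock_csv(inp["csv"], column_map=inp.get("column_map"))
    return _FIXTURES[inp["fixture"]](seed=cfg.seed)


def analyse_table(table: StockSeriesTable, cfg: AnalysisConfig,
                  raw_config: Mapping | None = None) -> AnalysisReport:
    """Run all three stages on an in-memory table."""
    segmentations = tuple(
        pelt_mean(
            table.column(name),
            penalty=aic_penalty(table.column(name)),
            min_segment_length=cfg.min_segment_length,
            years=table.years,
            series_name=name,
        )
        for name in cfg.changepoint_series
    )
    relationship_fits = tuple(fit_relationships(table, cfg))
    cusp_fit = fit_cusp(table, cfg.state_var, cfg.asym_var, cfg.bifur_var)
    alternatives = fit_alternatives(table, cfg.state_var, cfg.asym_var,
                                    cfg.bifur_var)
    validation = validate_cusp(cusp_fit, alternatives, seed=cfg.seed + 101)
    predicted = predict_states(cusp_fit, "nearest_mode")

    cfg_text = yaml.safe_dump(dict(raw_config or {}), sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_years": table.n,
        "parameters": {
            "changepoint_penalty": aic_penalty(),
            "min_segment_length": cfg.min_segment_length,
            "min_break_fraction": cfg.min_break_fraction,
            "max_breaks": cfg.max_breaks,
            "optimizer_starts": 8,
        },
        "reference_levels": None if cfg.reference_levels is None else vars(
            cfg.reference_levels),
        "generated_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return AnalysisReport(
        table=table,
        segmentations=segmentations,
        relationship_fits=relationship_fits,
        cusp_fit=cusp_fit,
        validation=validation,
        predicted_state=predicted,
        config=cfg,
        provenance=provenance,
    )


def summarize_regimes(report: AnalysisReport) -> pd.DataFrame:
    """Per-regime means of SSB, R, R/SSB, F and F/R, each variable scaled so
    its largest regime mean equals 1 (regimes from the SSB segmentation)."""
    table = report.table
    seg = next(
        (s for s in report.segmentations if s.series_name == "ssb"),
        report.segmentations[0],
    )
    bounds = (0,) + seg.changepoint_indices + (table.n,)
    rows = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        row = {"regime": i,
               "first_year": int(table.years[a]),
               "last_year": int(table.years[b - 1])}
        for var in ("ssb", "recruitment", "productivity", "f", "scaled_pressure"):
            row[var] = float(np.mean(table.column(var)[a:b]))
        rows.append(row)
    df = pd.DataFrame(rows)
    for var in ("ssb", "recruitment", "productivity", "f", "scaled_pressure"):
        df[var] = df[var] / df[var].max()
    return df


def run_full_analysis(config_path: str | Path,
                      out_dir: str | Path | None = None) -> AnalysisReport:
    """Validate the config, run the three stages and write the reports."""
    raw, cfg = load_config(config_path)
    table = _load_table(raw, cfg)
    report = analyse_table(table, cfg, raw_config=raw)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.table.to_csv(out / "input_table.csv")
    pd.DataFrame([s.to_dict() for s in report.segmentations]).to_csv(
        out / "segmentations.csv", index=False)
    rows = []
    for f in report.relationship_fits:
        for r in f.regimes:
            rows.append({"response": f.response_name, "covariate": f.covariate_name,
                         "first_year": r.first_year, "last_year": r.last_year,
                         "intercept": r.intercept, "slope": r.slope, "rss": r.rss})
    pd.DataFrame(rows).to_csv(out / "breakpoints.csv", index=False)
    per_year = pd.DataFrame([p.to_dict() for p in report.cusp_fit.per_year])
    per_year["predicted_state"] = report.predicted_state
    per_year["observed_state"] = report.table.column(report.cusp_fit.state_var)
    per_year.to_csv(out / "cusp_per_year.csv", index=False)
    summarize_regimes(report).to_csv(out / "regime_summary.csv", index=False)
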