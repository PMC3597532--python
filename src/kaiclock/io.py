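"""Configuration loading, CSV time-series I/O and screen-report artifacts.

CSV is the single tabular interchange format (column ``time_h`` plus one
column per channel, full float precision); JSON carries structured
results.  Configuration files are JSON or YAML with sections ``pto``,
``ttfl`` and ``feedback`` whose keys match the parameter dataclass
fields; unknown keys are rejected by schema validation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import fitting, metrics
from .params import (FeedbackSpec, PTOParameters, TTFLParameters,
                     default_pto, default_ttfl)
from .simulate import PerturbationProtocol, TimeSeries


class ConfigError(ValueError):
    """Invalid or unreadable configuration."""


_RATE4 = tuple[float, float, float, float]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PTOSection(_Section):
    tH_basal: _RATE4 | None = None
    tH_kaiA: _RATE4 | None = None
    tB_basal: _RATE4 | None = None
    beta_plus: float | None = None
    beta_minus: float | None = None
    kaiB_gate: _RATE4 | None = None
    k_hex: float | None = None
    K_P: float | None = None
    k_dis: float | None = None
    c_U: float | None = None
    c_S: float | None = None
    c_D: float | None = None
    K_dim: float | None = None
    K_seq: float | None = None
    K_half: float | None = None
    k_2bc: float | None = None
    k_4bc: float | None = None


class TTFLSection(_Section):
    k_1a: float | None = None
    k_1bc: float | None = None
    lam_act: float | None = None
    K_act: float | None = None
    lam_rep: float | None = None
    K_rep: float | None = None
    k_2: float | None = None
    k_3: float | None = None
    k_4: float | None = None


class FeedbackSection(_Section):
    activator: list[str] = ["T", "D"]
    repressor_pool: Literal["hexamer", "complex"] = "hexamer"
    repressor: list[str] = ["U"]


class ModelSection(_Section):
    pto: PTOSection = PTOSection()
    ttfl: TTFLSection = TTFLSection()
    feedback: FeedbackSection = FeedbackSection()


class ProtocolSection(_Section):
    kind: Literal["none", "knockout_kaiA", "overexpress_kaiA",
                  "overexpress_kaiC"] = "none"
    fold: float = 1.0
    trigger: float | Literal["at_mBC_minimum"] = "at_mBC_minimum"


class FitSection(_Section):
    n_starts: int = Field(3, ge=1)
    budget: int = Field(2000, ge=1)
    seed: int = 0
    bound_decades: float = Field(2.0, gt=0)


class MetricsSection(_Section):
    period_window: tuple[float, float] = metrics.PERIOD_WINDOW
    mrna_phase_window: tuple[float, float] = metrics.MRNA_PHASE_WINDOW
    ukaic_phase_window: tuple[float, float] = metrics.UKAIC_PHASE_WINDOW
    pkaic_phase_window: tuple[float, float] = metrics.PKAIC_PHASE_WINDOW
    pkaic_floor: float = metrics.PKAIC_FLOOR


class PathsSection(_Section):
    data: str | None = None
    outdir: str = "."


class RunConfig(_Section):
    paths: PathsSection = PathsSection()
    model: ModelSection = ModelSection()
    protocol: ProtocolSection = ProtocolSection()
    fit: FitSection = FitSection()
    metrics: MetricsSection = MetricsSection()
    logging: Literal["debug", "info", "warning", "error"] = "info"

    #: names of pto/ttfl fields filled from the calibrated-not-measured
    #: default set rather than the file (populated by load_config)
    calibrated_defaults: list[str] = []

    def pto_parameters(self) -> PTOParameters:
        given = {k: v for k, v in self.model.pto.model_dump().items()
                 if v is not None}
        base = dataclasses.asdict(default_pto())
        base.update(given)
        return PTOParameters(**base)

    def ttfl_parameters(self) -> TTFLParameters:
        given = {k: v for k, v in self.model.ttfl.model_dump().items()
                 if v is not None}
        base = dataclasses.asdict(default_ttfl())
        base.update(given)
        return TTFLParameters(**base)

    def feedback_spec(self) -> FeedbackSpec:
        fb = self.model.feedback
        return FeedbackSpec(activator_states=frozenset(fb.activator),
                            repressor_pool=fb.repressor_pool,
                            repressor_states=frozenset(fb.repressor))

    def perturbation_protocol(self) -> PerturbationProtocol:
        pr = self.protocol
        return PerturbationProtocol(kind=pr.kind, fold=pr.fold,
                                    trigger=pr.trigger)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Missing pto/ttfl values fall back to the calibrated defaults; the
    names of those fields are recorded in ``calibrated_defaults`` so a
    run log can flag which rates were not user-supplied.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix.lower() == ".json" \
            else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"{path}: invalid key or value at {loc!r}: "
                          f"{first['msg']}") from exc
    cfg.calibrated_defaults = sorted(
        [f"pto.{k}" for k, v in cfg.model.pto.model_dump().items() if v is None]
        + [f"ttfl.{k}" for k, v in cfg.model.ttfl.model_dump().items()
           if v is None])
    # validate cross-field constraints eagerly so errors name the section
    try:
        cfg.pto_parameters()
        cfg.ttfl_parameters()
        cfg.feedback_spec()
        cfg.perturbation_protocol()
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    payload = cfg.model_dump(exclude={"calibrated_defaults"})
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Time series CSV
# ---------------------------------------------------------------------------

class TimeSeriesFormatError(ValueError):
    """Malformed time-series CSV."""


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """Write a time series as CSV at full float precision."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a time-series CSV; validates header and strict time monotony.

    Errors carry the offending line number (header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TimeSeriesFormatError(f"{path}: no data") from exc
    if df.empty:
        raise TimeSeriesFormatError(f"{path}: no data rows")
    if "time_h" not in df.columns:
        raise TimeSeriesFormatError(f"{path}: line 1: missing 'time_h' column")
    if len(df.columns) < 2:
        raise TimeSeriesFormatError(f"{path}: line 1: no channel columns")
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise TimeSeriesFormatError(
            f"{path}: line {int(bad[0]) + 3}: time_h not strictly increasing")
    return TimeSeries(t, {c: df[c].to_numpy(dtype=float)
                          for c in df.columns if c != "time_h"})


# ---------------------------------------------------------------------------
# Screen report artifacts
# ---------------------------------------------------------------------------

_SCREEN_COLUMNS = ["spec", "group", "activator", "repressor_pool", "repressor",
                   "cost", "period_h", "wildtype_verdict", "wildtype_reasons",
                   "kaiA_knockout", "oxkaiA_threshold_fold", "oxkaiA",
                   "oxKaiC", "survives_funnel", "error"]


def _row_record(row: fitting.ScreenRow) -> dict:
    best = row.best
    mut = row.mutants
    diag = best.diagnostics if best else None

    def verdict(c):
        return "" if c is None else ("pass" if (getattr(c, "good", c)) else "fail")

    return {
        "spec": row.spec.name,
        "group": row.group,
        "activator": "".join(sorted(row.spec.activator_states)),
        "repressor_pool": row.spec.repressor_pool,
        "repressor": "".join(sorted(row.spec.repressor_states)),
        "cost": best.cost if best else np.nan,
        "period_h": (diag.period if diag and diag.period else np.nan),
        "wildtype_verdict": best.classification.verdict if best else "",
        "wildtype_reasons": "; ".join(best.classification.reasons) if best else "",
        "kaiA_knockout": verdict(mut.kaia_knockout) if mut else "",
        "oxkaiA_threshold_fold": (mut.oxkaia_threshold if mut and
                                  mut.oxkaia_threshold is not None else np.nan),
        "oxkaiA": verdict(mut.oxkaia_pass) if mut else "",
        "oxKaiC": verdict(mut.oxkaic_pass) if mut else "",
        "survives_funnel": row.survives_funnel,
        "error": row.error or "",
    }


def report_screen(report: fitting.ScreenReport, path_prefix: str | Path
                  ) -> tuple[Path, Path]:
    """Write a screen report as a CSV summary plus a full JSON artifact.

    Returns the (csv_path, json_path) pair.  Row order and column order
    are deterministic (enumeration order).
    """
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")

    records = [_row_record(r) for r in report.rows]
    pd.DataFrame.from_records(records)[_SCREEN_COLUMNS].to_csv(
        csv_path, index=False)

    def jsonable(rec):
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in rec.items()}

    payload = {
        "seed": report.seed,
        "good_fit_count": report.good_fit_count(),
        "good_fit_count_group_I": report.good_fit_count("I"),
        "good_fit_count_group_II": report.good_fit_count("II"),
        "survivors": report.survivors,
        "rows": [jsonable(r) | {
            "params": (dataclasses.asdict(report.rows[i].best.params)
                       if report.rows[i].best else None),
            "peak_phase": (report.rows[i].best.diagnostics.peak_phase
                           if report.rows[i].best
                           and report.rows[i].best.diagnostics else None),
        } for i, r in enumerate(records)],
    }
    json_path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    return csv_path, json_path
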