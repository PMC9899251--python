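"""File formats: trace CSV + sidecar metadata, saturation-curve CSV, JSON reports.

Formats are deliberately plain: UTF-8 CSV with '.' decimal and comma
separator, and JSON reports carrying a ``schema_version`` field.  Report
writing is deterministic (sorted keys, fixed float formatting) so identical
inputs produce byte-identical reports.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calorimetry import TemperatureTrace
from .chamber import SaturationCurve
from .errors import ConfigurationError

SCHEMA_VERSION = 1

TRACE_COLUMNS = ["time_s", "temperature_K"]
CURVE_COLUMNS = ["voltage_V", "reading", "reading_sd"]


def _meta_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trace(trace: TemperatureTrace, csv_path, meta_path=None) -> None:
    """Write a trace as ``time_s,temperature_K`` CSV plus a JSON sidecar.

    The sidecar carries the irradiation window and sample rate, which the CSV
    itself cannot express.
    """
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": trace.times, "temperature_K": trace.temperatures})
    df.to_csv(csv_path, index=False, float_format="%.9f")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "irradiation_start_s": trace.irradiation_start,
        "irradiation_end_s": trace.irradiation_end,
        "sample_rate_hz": trace.sample_rate,
    }
    write_report(meta, meta_path or _meta_path(csv_path))


def read_trace(csv_path, meta_path=None) -> TemperatureTrace:
    """Read a trace CSV and its sidecar metadata back into a TemperatureTrace."""
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise ConfigurationError(f"malformed trace CSV {csv_path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trace CSV {csv_path} missing columns {missing}")
    meta_path = Path(meta_path) if meta_path else _meta_path(csv_path)
    if not meta_path.exists():
        raise ConfigurationError(f"trace sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    return TemperatureTrace(
        times=df["time_s"].to_numpy(float),
        temperatures=df["temperature_K"].to_numpy(float),
        irradiation_start=float(meta["irradiation_start_s"]),
        irradiation_end=float(meta["irradiation_end_s"]),
        sample_rate=float(meta.get("sample_rate_hz", 5.0)),
    )


def write_curve(curve: SaturationCurve, path) -> None:
    """Write a saturation curve as ``voltage_V,reading,reading_sd`` CSV."""
    sd = curve.reading_sd if curve.reading_sd is not None else np.zeros(len(curve))
    pd.DataFrame(
        {"voltage_V": curve.voltages, "reading": curve.readings, "reading_sd": sd}
    ).to_csv(path, index=False, float_format="%.10g")


def read_curve(path) -> SaturationCurve:
    """Read a saturation-curve CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ConfigurationError(f"malformed curve CSV {path}: {exc}") from exc
    missing = [c for c in ("voltage_V", "reading") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"curve CSV {path} missing columns {missing}")
    sd = df["reading_sd"].to_numpy(float) if "reading_sd" in df.columns else None
    return SaturationCurve(
        voltages=df["voltage_V"].to_numpy(float),
        readings=df["reading"].to_numpy(float),
        reading_sd=sd,
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path) -> None:
    """Write a JSON report deterministically (sorted keys, trailing newline)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(report)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    text = json.dumps(_jsonable(payload), indent=2, sort_keys=True)
    path.write_text(text + "\n", encoding="utf-8")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
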