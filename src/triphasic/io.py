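"""Delimited-text readers/writers for cohort tables and configuration files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SPIKES_COLUMNS = ["recording_id", "unit_id", "spike_time_s"]
UNITS_COLUMNS = ["recording_id", "unit_id", "area", "depth_frac", "is_single", "is_pv_true"]
TRIALS_COLUMNS = ["recording_id", "event_time_s", "protocol", "lag_ms", "hand_on",
                  "intensity_frac"]


class TableFormatError(ValueError):
    pass


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise TableFormatError(
                f"{path}: cannot parse {col}={df[col].iloc[row]!r} at data row {row}")
        df[col] = coerced
    return df


def read_spikes(path) -> pd.DataFrame:
    df = _read_table(path, SPIKES_COLUMNS, ["spike_time_s"])
    if (df["spike_time_s"] < 0).any():
        raise TableFormatError(f"{path}: spike times must be non-negative")
    return df


def read_units(path) -> pd.DataFrame:
    df = _read_table(path, ["recording_id", "unit_id", "area", "depth_frac"],
                     ["depth_frac"])
    return df


def read_trials(path) -> pd.DataFrame:
    df = _read_table(path, ["recording_id", "event_time_s", "protocol"],
                     ["event_time_s", "lag_ms", "intensity_frac"])
    if "lag_ms" not in df.columns:
        df["lag_ms"] = np.nan
    if "intensity_frac" not in df.columns:
        df["intensity_frac"] = 1.0
    if "hand_on" not in df.columns:
        df["hand_on"] = df["protocol"].isin(
            ["hand", "paired_pulse", "hand_plus_cortex"]).astype(int)
    return df


def read_probe_coords(manifest_path) -> dict:
    """Probe coordinates from a cohort manifest.json."""
    payload = json.loads(Path(manifest_path).read_text())
    return {rec: {area: tuple(xy) for area, xy in areas.items()}
            for rec, areas in payload.get("probe_coords", {}).items()}


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
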