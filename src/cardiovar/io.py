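"""Reading and writing the pipeline's table formats.

Traces travel as long-format CSV (``well_id,time_s,rfu``), metadata and
per-well beat parameters as plain CSV, run configuration as YAML.  All
formats are plain text so runs diff cleanly under version control.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beatcall import CalciumTrace
from .trace_sim import PopulationConfig

TRACE_COLUMNS = ["well_id", "time_s", "rfu"]


def traces_to_frame(traces: list[CalciumTrace]) -> pd.DataFrame:
    frames = [
        pd.DataFrame({
            "well_id": tr.well_id,
            "time_s": tr.times,
            "rfu": tr.values,
        })
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: list[CalciumTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.4f")


def read_traces_csv(path: str | Path) -> list[CalciumTrace]:
    """Load a long-format trace table into per-well traces.

    Sampling rate and duration are inferred from each well's time grid.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for well_id, grp in df.groupby("well_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: well {well_id} has fewer than 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise ValueError(f"{path}: well {well_id} is not uniformly sampled")
        rate = 1.0 / dt[0]
        traces.append(
            CalciumTrace(
                well_id=str(well_id),
                sampling_rate=rate,
                values=grp["rfu"].to_numpy(dtype=float),
                duration=len(t) / rate,
            )
        )
    return traces


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def population_config_from_dict(d: dict) -> PopulationConfig:
    known = {f.name for f in PopulationConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown population config keys: {sorted(unknown)}")
    if "concentration_grid" in d:
        d = {**d, "concentration_grid": tuple(d["concentration_grid"])}
    return PopulationConfig(**d)


def config_hash(cfg: dict) -> str:
    """Stable digest of the semantically meaningful config content."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
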