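"""Readers and writers for traces, profiles, configs and run logs.

Column dialects are fixed (snake_case, units embedded in the name):

* traces: CSV with ``time_s, h2s_uM, pH, temp_C, salinity, event`` where
  ``event`` is empty, ``spike`` or ``pasteurization``; generator ground
  truth travels in a ``<name>.truth.json`` sidecar.  The total-sulfide
  channel is not stored: it is recomputed from the H2S channel through the
  speciation correction on read, so a written-then-read trace exercises the
  full correction path.
* profiles: TSV with ``depth_m`` first, then any observation columns
  (``sigma_theta, s2_uM, o2_uM, ca_epsy914_cells_per_l, f_sulfurimonas``,
  Mn species in nM, ...).
* model configs: YAML or JSON mirroring the ModelConfig fields.

All writers are deterministic given their inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import SensorTrace
from .profiles import DepthProfile
from .speciation import total_sulfide
from .transport import ModelConfig

__all__ = [
    "write_trace",
    "read_trace",
    "trace_to_dataframe",
    "trace_from_dataframe",
    "write_profile",
    "read_profile",
    "read_model_config",
    "write_model_config",
    "config_hash",
    "write_run_log",
]

_FLOAT_FMT = "%.17g"  # exact float round-trip


def trace_to_dataframe(trace: SensorTrace) -> pd.DataFrame:
    event_col = [""] * len(trace.time)
    for t_ev, kind in trace.events:
        idx = int(np.argmin(np.abs(trace.time - t_ev)))
        event_col[idx] = kind
    return pd.DataFrame(
        {
            "time_s": trace.time,
            "h2s_uM": trace.h2s,
            "pH": trace.pH,
            "temp_C": trace.temp_C,
            "salinity": trace.salinity,
            "event": event_col,
        }
    )


def trace_from_dataframe(df: pd.DataFrame, truth: dict | None = None) -> SensorTrace:
    required = {"time_s", "h2s_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace is missing required columns: {sorted(missing)}")
    pH = float(df["pH"].iloc[0]) if "pH" in df else 7.0
    temp_C = float(df["temp_C"].iloc[0]) if "temp_C" in df else 10.0
    salinity = float(df["salinity"].iloc[0]) if "salinity" in df else 22.0
    time = df["time_s"].to_numpy(dtype=float)
    h2s = df["h2s_uM"].to_numpy(dtype=float)
    events: list[tuple[float, str]] = []
    if "event" in df:
        ev = df["event"].fillna("").astype(str)
        for t, kind in zip(time, ev):
            if kind:
                events.append((float(t), kind))
    return SensorTrace(
        time=time,
        h2s=h2s,
        total_sulfide=total_sulfide(h2s, pH, temp_C, salinity),
        pH=pH,
        temp_C=temp_C,
        salinity=salinity,
        events=events,
        truth=truth,
    )


def _truth_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth.json")


def write_trace(trace: SensorTrace, path: str | Path) -> None:
    path = Path(path)
    trace_to_dataframe(trace).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if trace.truth is not None:
        _truth_sidecar(path).write_text(
            json.dumps(trace.truth, indent=2, sort_keys=True) + "\n"
        )


def read_trace(path: str | Path) -> SensorTrace:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    truth = None
    sidecar = _truth_sidecar(path)
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return trace_from_dataframe(df, truth=truth)


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    path = Path(path)
    profile.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if profile.truth is not None:
        _truth_sidecar(path).write_text(
            json.dumps(profile.truth, indent=2, sort_keys=True) + "\n"
        )


def read_profile(path: str | Path) -> DepthProfile:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "depth_m" not in df.columns:
        raise ValueError(f"{path}: missing required depth_m column")
    truth = None
    sidecar = _truth_sidecar(path)
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    try:
        return DepthProfile(data=df, label=path.stem, truth=truth)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_model_config(path: str | Path) -> ModelConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of ModelConfig fields")
    return ModelConfig.from_dict(raw)


def write_model_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(out_path: str | Path, **entries) -> Path:
    """Write the machine-readable run log next to an output file.

    Records the package version, a config hash of the entries, and whatever
    the caller passes (seed, derived time step, iteration counts, ...).
    """
    from . import __version__

    out_path = Path(out_path)
    log_path = out_path.with_suffix(out_path.suffix + ".log.json")
    payload = {"mnsox_version": __version__, "config_hash": config_hash(entries)}
    payload.update(entries)
    log_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return log_path
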