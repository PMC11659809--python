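"""CSV/JSON readers and writers for measurements, trajectories and rates.

Schemas
-------
Measurement CSV: columns ``time_h, component, value, unit, exclude`` (exclude
is 0/1).  Trajectory CSV (tidy): ``time_h, variable, value, unit, regime``.
Rate CSV: ``time_h, rate_name, value, unit``.  Parameter files and fit
results are flat JSON (see :mod:`lacshift.parameters` and
:class:`lacshift.fitting.FitResult`).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .kinetics import COMPONENT_UNITS
from .rates import MeasurementSeries, RateSeries
from .simulate import Trajectory

__all__ = ["read_measurements_csv", "write_measurements_csv",
           "write_trajectory_csv", "write_rates_csv", "write_run_log"]

MEASUREMENT_COLUMNS = ("time_h", "component", "value", "unit", "exclude")


def read_measurements_csv(path) -> Dict[str, MeasurementSeries]:
    """Read a tidy measurement table into per-component series."""
    df = pd.read_csv(path)
    missing = set(("time_h", "component", "value")) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "exclude" not in df.columns:
        df["exclude"] = 0
    out = {}
    for comp, grp in df.groupby("component", sort=False):
        grp = grp.sort_values("time_h")
        unit = str(grp["unit"].iloc[0]) if "unit" in grp.columns else ""
        out[str(comp)] = MeasurementSeries(
            str(comp), grp["time_h"].to_numpy(dtype=float),
            grp["value"].to_numpy(dtype=float), unit=unit,
            exclude=grp["exclude"].to_numpy().astype(bool))
    return out


def write_measurements_csv(measurements: Mapping[str, MeasurementSeries],
                           path) -> None:
    rows = []
    for comp, s in measurements.items():
        rows.append(pd.DataFrame({
            "time_h": s.times, "component": comp, "value": s.values,
            "unit": s.unit or COMPONENT_UNITS.get(comp, ""),
            "exclude": s.exclude.astype(int),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path, tidy: bool = True) -> None:
    (traj.to_tidy() if tidy else traj.to_frame()).to_csv(path, index=False)


def write_rates_csv(rates: Mapping[str, RateSeries], path) -> None:
    rows = []
    for name, rs in rates.items():
        rows.append(pd.DataFrame({
            "time_h": rs.times, "rate_name": name,
            "value": rs.values, "unit": rs.unit,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_log(out_path, command: str, inputs: Mapping[str, str],
                  options: Mapping) -> Path:
    """Sidecar JSON log: inputs (with content hashes), options, version.

    For deterministic commands the log carries everything needed to
    regenerate the output bit-identically.
    """
    from . import __version__

    log = {
        "command": command,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                   for k, p in inputs.items() if p is not None},
        "options": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                        else str(v)) for k, v in options.items()},
    }
    log_path = Path(str(out_path) + ".log.json")
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    return log_path
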