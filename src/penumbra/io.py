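"""File formats: profile CSV, two-column tables, metrics/comparison JSON, 2D maps.

Fixed CSV dialect for reproducibility: '.' decimal, comma separator, one
header line, 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ProfileComparison, ProfileMetrics
from .oracle import OracleResult
from .projection import IntensityMap, Profile

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "read_two_column",
    "write_metrics_json",
    "write_comparison_json",
    "write_oracle_csv",
    "write_map",
    "read_map",
]

_FMT = "%.9g"


def write_profile_csv(profile: Profile, path: str | Path) -> None:
    """Two columns ``r_mm,intensity``, one header line."""
    with open(path, "w") as fh:
        fh.write("r_mm,intensity\n")
        for r, v in zip(profile.positions, profile.values):
            fh.write(f"{r:.9g},{v:.9g}\n")


def read_profile_csv(path: str | Path) -> Profile:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Profile(data[:, 0], np.maximum(data[:, 1], 0.0))


def read_two_column(path: str | Path) -> np.ndarray:
    """Read (position, value) rows from delimited text; header optional."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    first = df.iloc[0]
    try:
        [float(x) for x in first]
    except (TypeError, ValueError):
        df = df.iloc[1:]
    arr = df.astype(float).to_numpy()
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited columns")
    return arr[:, :2]


def write_metrics_json(metrics: ProfileMetrics, path: str | Path, extra: dict | None = None) -> None:
    payload = metrics.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_comparison_json(comparison: ProfileComparison, path: str | Path) -> None:
    Path(path).write_text(json.dumps(comparison.to_dict(), indent=2, sort_keys=True) + "\n")


def write_oracle_csv(result: OracleResult, path: str | Path) -> None:
    """Same layout as the profile CSV, plus a standard-error column for MC."""
    with open(path, "w") as fh:
        if result.standard_errors is None:
            fh.write("r_mm,intensity\n")
            for r, v in zip(result.positions, result.values):
                fh.write(f"{r:.9g},{v:.9g}\n")
        else:
            fh.write("r_mm,intensity,standard_error\n")
            for r, v, s in zip(result.positions, result.values, result.standard_errors):
                fh.write(f"{r:.9g},{v:.9g},{s:.9g}\n")


def write_map(imap: IntensityMap, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Dense CSV matrix (rows = x, columns = y) with a JSON grid sidecar."""
    np.savetxt(csv_path, imap.values, delimiter=",", fmt=_FMT)
    if meta_path is None:
        meta_path = Path(csv_path).with_suffix(".json")
    meta = dict(imap.meta)
    meta.update(
        {
            "x_min": float(imap.x[0]),
            "x_max": float(imap.x[-1]),
            "y_min": float(imap.y[0]),
            "y_max": float(imap.y[-1]),
            "shape": list(imap.values.shape),
        }
    )
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_map(csv_path: str | Path, meta_path: str | Path | None = None) -> IntensityMap:
    if meta_path is None:
        meta_path = Path(csv_path).with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    x = np.linspace(meta["x_min"], meta["x_max"], values.shape[0])
    y = np.linspace(meta["y_min"], meta["y_max"], values.shape[1])
    return IntensityMap(x, y, values, meta)
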