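"""CSV/JSON readers and writers for all pipeline artifacts.

Everything is plain text: timeseries as CSV with named headers (column order
irrelevant), camera models and reports as JSON.  Numeric round-trips are
lossless to well below 1e-12 (full repr precision).  Malformed rows are
reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_json",
    "write_json",
    "MARKER_COLUMNS",
    "EYE_COLUMNS",
    "FUSED_COLUMNS",
]

MARKER_COLUMNS = ["timestamp", "x0", "y0", "x1", "y1", "x2", "y2", "x3", "y3", "valid"]
EYE_COLUMNS = ["timestamp", "x_px", "y_px", "valid"]
POSE_COLUMNS = ["timestamp", "yaw_deg", "pitch_deg", "roll_deg",
                "tx_m", "ty_m", "tz_m", "valid"]
ANGLE_COLUMNS = ["timestamp", "azimuth_deg", "elevation_deg", "valid"]
FUSED_COLUMNS = ["time", "E_deg", "H_deg", "G_deg",
                 "dE_dps", "dH_dps", "dG_dps", "valid"]


def read_timeseries_csv(path: str | Path, required_columns,
                        time_column: str | None = None,
                        monotone: bool = True) -> pd.DataFrame:
    """Read a timeseries CSV, validating schema and timestamp order.

    ``time_column`` defaults to the first required column.  A non-monotone
    timestamp raises an error naming the offending line (1-based, counting
    the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    tc = time_column or required_columns[0]
    t = df[tc].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        line = int(np.flatnonzero(~np.isfinite(t))[0]) + 2
        raise ValueError(f"{path.name}: non-finite timestamp at line {line}")
    if monotone and len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            line = int(bad[0]) + 3  # +1 diff shift, +1 header, +1 one-based
            raise ValueError(f"{path.name}: non-monotone timestamp at line {line}")
    return df


def write_timeseries_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write with full float precision so round-trips are lossless."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
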