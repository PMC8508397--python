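"""CSV readers/writers for all series interfaces.

Every persisted table is a plain CSV with a header row, ISO-8601 UTC
timestamps in a ``timestamp`` column (or ``date`` for daily tables), and
numeric value columns; missing values are empty fields.  Local time is never
serialised — it is derived from station metadata at presentation time only.

``read_series``/``write_series`` round-trip: timestamps are reproduced
exactly and values to better than 1e-9.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .filtering import LABELS

#: Known table schemas: name -> (time column, value columns, kind).
SCHEMAS = {
    "uvi": {"time": "timestamp", "columns": ["uvi"], "kind": "series"},
    "cf": {"time": "timestamp", "columns": ["cf_total", "cf_thick", "cf_thin"], "kind": "frame"},
    "toc": {"time": "date", "columns": ["toc"], "kind": "daily"},
    "mask": {"time": "timestamp", "columns": ["label"], "kind": "labels"},
    "estimates": {
        "time": "timestamp",
        "columns": ["latitude", "longitude", "uvi", "source", "sky"],
        "kind": "points",
    },
    "dose": {"time": "timestamp", "columns": ["sed", "csed"], "kind": "frame"},
}


def _parse_times(raw: pd.Series, column: str, daily: bool) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", utc=not daily, format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ParseError(f"row {row}: malformed {column} {raw[bad].iloc[0]!r}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0]) + 2
        raise ParseError(f"row {row}: missing {column}")
    idx = pd.DatetimeIndex(parsed)
    diffs = np.diff(idx.asi8)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 3
        raise ParseError(f"row {row}: {column}s not strictly increasing")
    return idx


def read_series(path, schema: str):
    """Read a typed series/table from CSV.

    Parameters
    ----------
    path : path-like
    schema : str
        One of ``uvi, cf, toc, mask, estimates, dose``.

    Returns
    -------
    pandas.Series or pandas.DataFrame
        A Series for single-column schemas, a DataFrame otherwise, indexed
        by UTC timestamp (or date for daily tables).

    Raises
    ------
    ParseError
        Naming the offending row for malformed or non-monotone timestamps,
        non-numeric values, or unknown columns.
    """
    if schema not in SCHEMAS:
        raise ParseError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})

    expected = [spec["time"], *spec["columns"]]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ParseError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")

    idx = _parse_times(df[spec["time"]], spec["time"], daily=spec["kind"] == "daily")

    out = pd.DataFrame(index=idx)
    for col in spec["columns"]:
        if col in ("source", "sky", "label"):
            out[col] = df[col].to_numpy()
            if col == "label":
                bad = ~pd.Series(out[col]).isin(LABELS).to_numpy()
                if bad.any():
                    row = int(np.flatnonzero(bad)[0]) + 2
                    raise ParseError(f"row {row}: invalid label {out[col][bad][0]!r}")
        else:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise ParseError(f"row {row}: non-numeric {col} {df[col][bad].iloc[0]!r}")
            out[col] = vals.to_numpy(dtype=float)

    if spec["kind"] == "daily":
        out.index = out.index.normalize()
        out.index.name = "date"
    else:
        out.index.name = "timestamp"

    if len(spec["columns"]) == 1:
        series = out[spec["columns"][0]]
        series.attrs["schema"] = schema
        return series
    out.attrs["schema"] = schema
    return out


def write_series(obj, path, schema: str) -> None:
    """Write a series/table to CSV in the given schema (see read_series)."""
    if schema not in SCHEMAS:
        raise ParseError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    df = obj.to_frame() if isinstance(obj, pd.Series) else obj.copy()
    df = df[[c for c in spec["columns"] if c in df.columns]]

    idx = df.index
    if spec["kind"] == "daily":
        time_str = pd.DatetimeIndex(idx).strftime("%Y-%m-%d")
    else:
        dt = pd.DatetimeIndex(idx)
        if dt.tz is None:
            dt = dt.tz_localize("UTC")
        time_str = dt.tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")

    out = df.copy()
    out.insert(0, spec["time"], time_str)
    out.to_csv(path, index=False, float_format="%.12g")
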