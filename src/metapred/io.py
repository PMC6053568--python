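"""Reading, writing and validating long-format population time series.

The on-disk format is tidy CSV with header ``run_id,patch_id,time,H,P``
(UTF-8, comma-delimited, '.' decimal; integer counts round-trip bit-exactly).
Extra columns are preserved.  Every output file can carry a JSON metadata
sidecar recording the parameters, seed and package version that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "TimeSeriesSchemaError",
    "validate_timeseries",
    "read_timeseries",
    "write_timeseries",
    "write_metadata",
]

REQUIRED_COLUMNS = ("run_id", "patch_id", "time", "H", "P")


class TimeSeriesSchemaError(ValueError):
    """A time-series table violates the long-format schema."""


def _offending_rows(mask: pd.Series, limit: int = 5) -> str:
    idx = [int(i) for i in np.flatnonzero(mask.to_numpy())[:limit]]
    return f"rows {idx}"


def validate_timeseries(ts: pd.DataFrame) -> pd.DataFrame:
    """Validate schema; returns the frame with count columns coerced to int64.

    Raises :class:`TimeSeriesSchemaError` with row-level messages on missing
    columns, negative or non-integer counts, or duplicate (run, patch, time)
    combinations.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in ts.columns]
    if missing:
        raise TimeSeriesSchemaError(f"missing required columns: {missing}")
    ts = ts.copy()
    for col in ("H", "P"):
        values = pd.to_numeric(ts[col], errors="coerce")
        bad = values.isna() & ts[col].notna() | values.isna()
        if len(ts) and bad.any():
            raise TimeSeriesSchemaError(
                f"column {col}: non-numeric values at {_offending_rows(bad)}"
            )
        nonint = values.notna() & (values != values.round())
        if nonint.any():
            raise TimeSeriesSchemaError(
                f"column {col}: non-integer counts at {_offending_rows(nonint)}"
            )
        neg = values < 0
        if neg.any():
            raise TimeSeriesSchemaError(
                f"column {col}: negative counts at {_offending_rows(neg)}"
            )
        ts[col] = values.astype(np.int64) if len(ts) else ts[col].astype(np.int64)
    dup = ts.duplicated(subset=["run_id", "patch_id", "time"], keep=False)
    if dup.any():
        raise TimeSeriesSchemaError(
            f"duplicate (run_id, patch_id, time) combinations at {_offending_rows(dup)}"
        )
    return ts


def read_timeseries(path) -> pd.DataFrame:
    """Read and validate a long-format CSV; an empty file yields an empty
    frame with a valid schema."""
    path = Path(path)
    try:
        ts = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        ts = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return validate_timeseries(ts)


def write_timeseries(ts: pd.DataFrame, path) -> None:
    """Validate and write a long-format CSV (round-trips exactly)."""
    validate_timeseries(ts).to_csv(path, index=False)


def write_metadata(path, payload: dict) -> None:
    """Write a JSON metadata sidecar with a content hash of the payload."""
    from . import __version__

    body = dict(payload)
    body["package"] = {"name": "metapred", "version": __version__}
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=str).encode()
    ).hexdigest()
    body["config_sha256"] = digest
    Path(path).write_text(json.dumps(body, indent=2, default=str) + "\n")
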