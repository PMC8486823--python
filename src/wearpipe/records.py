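"""Event-record containers and delimited-text readers/writers.

An *event record* is one timestamped observation for one user: a heart-rate
sample in bpm, a step count, or a categorical sleep stage.  In memory an
event table is a :class:`pandas.DataFrame` with the canonical columns
``user_id, stream, timestamp, value, unit``; timestamps are UTC instants
with at least second precision.  Files are RFC-4180 CSV with ISO-8601
timestamps and empty fields for missing values.

Malformed rows are never silently dropped: every reader returns the clean
table together with a rejects table carrying the offending raw row and a
machine-readable reason.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import EVENT_COLUMNS, LABEL_COLUMNS, SLEEP_TOKENS, Stream

logger = logging.getLogger(__name__)

_VALID_STREAMS = frozenset(s.value for s in Stream)
_SLEEP_SET = frozenset(SLEEP_TOKENS)


class ReadResult(NamedTuple):
    """Clean events plus a rejects report (raw row index, column dump, reason)."""

    events: pd.DataFrame
    rejects: pd.DataFrame


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": pd.Series(dtype=str),
            "stream": pd.Series(dtype=str),
            "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
            "value": pd.Series(dtype=object),
            "unit": pd.Series(dtype=str),
        }
    )


def read_events(path: str | Path, schema: dict[str, str] | None = None) -> ReadResult:
    """Read an event CSV into the canonical table.

    Parameters
    ----------
    path : path to a CSV with at least user/stream/timestamp/value columns.
    schema : optional mapping from file column names to canonical names
        (``user_id, stream, timestamp, value, unit``).

    Returns
    -------
    ReadResult
        ``events`` sorted by ``(user_id, stream, timestamp)``; ``rejects``
        with one row per malformed input row and a ``reason`` column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=schema)
    missing_cols = [c for c in ("user_id", "stream", "timestamp", "value") if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"event file {path} lacks required columns: {missing_cols}")
    if "unit" not in raw.columns:
        raw["unit"] = ""
    raw = raw[list(EVENT_COLUMNS)]

    reasons = pd.Series("", index=raw.index, dtype=object)

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True, format="ISO8601")
    reasons[ts.isna() & (reasons == "")] = "bad_timestamp"

    bad_stream = ~raw["stream"].isin(_VALID_STREAMS)
    reasons[bad_stream & (reasons == "")] = "bad_stream"

    value: pd.Series = raw["value"].copy().astype(object)
    numeric_mask = raw["stream"].isin([Stream.heart_rate.value, Stream.steps.value])
    num = pd.to_numeric(raw.loc[numeric_mask, "value"], errors="coerce")
    bad_numeric = num.index[num.isna() | ~np.isfinite(num)]
    reasons[reasons.index.isin(bad_numeric) & (reasons == "")] = "bad_value"
    # heart rate must be strictly positive at ingest; the <20 bpm cleaning
    # threshold is applied later in harmonization, not here
    hr_rows = num.index[(raw.loc[numeric_mask, "stream"] == Stream.heart_rate.value) & (num <= 0)]
    reasons[reasons.index.isin(hr_rows) & (reasons == "")] = "bad_value"
    value.loc[numeric_mask] = num

    sleep_mask = raw["stream"] == Stream.sleep.value
    bad_sleep = sleep_mask & ~raw["value"].isin(_SLEEP_SET)
    reasons[bad_sleep & (reasons == "")] = "bad_sleep_token"

    ok = reasons == ""
    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]
    rejects = rejects.reset_index(names="row")

    events = raw.loc[ok].copy()
    events["timestamp"] = ts[ok]
    events["value"] = value[ok]
    events = events.sort_values(
        ["user_id", "stream", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    if rejects.shape[0]:
        logger.warning("read_events: %d rows rejected from %s", rejects.shape[0], path)
    if events.empty:
        events = _empty_events()
    return ReadResult(events, rejects)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table to CSV with ISO-8601 timestamps."""
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out[list(EVENT_COLUMNS)].to_csv(path, index=False)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular artifact as CSV; missing cells become empty fields."""
    rows.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tabular artifact written by :func:`write_table`."""
    return pd.read_csv(path)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read per-user labels; unknown labels come back as NaN.

    The table has one row per user with binary ``phenotype`` (e.g.
    insulin-resistant = 1 / insulin-sensitive = 0) and binary ``sex``.
    """
    labels = pd.read_csv(path, dtype={"user_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise ValueError(f"labels file {path} lacks columns: {missing}")
    if labels["user_id"].duplicated().any():
        raise ValueError("labels file has duplicate user_id rows")
    return labels[list(LABEL_COLUMNS)]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels[list(LABEL_COLUMNS)].to_csv(path, index=False)
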