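"""Raw event streams -> cleaned, smoothed per-user 1-minute series.

Preprocessing is strictly per individual: sleep stages are binarized,
all streams are aggregated onto a regular 1-minute grid, physiologically
implausible heart-rate values (below the configured floor, default 20 bpm)
are removed, and the series are smoothed with a trailing 5-minute rolling
mean (heart rate, steps) or rolling max (binarized sleep).  Gaps remain
gaps: no imputation is applied anywhere, so downstream summary statistics
are computed on available data only.

The harmonized container is a long table with columns
``user_id, stream, minute, value`` where ``minute`` is a UTC instant on an
exact 60-second lattice and ``value`` is float (NaN = missing).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .params import SLEEP_BINARIZATION, PipelineParams, Stream

logger = logging.getLogger(__name__)

MINUTE_COLUMNS = ("user_id", "stream", "minute", "value")


def binarize_sleep(category: str, mapping: dict[str, int | None] | None = None) -> float:
    """Map one of the eight sleep-stage tokens to 1 (asleep), 0 (awake) or NaN.

    Asleep-like stages (asleep, light, deep, restless, REM) map to 1,
    awake-like (awake, wake) to 0, and ``unknown`` to missing.
    """
    mapping = SLEEP_BINARIZATION if mapping is None else mapping
    if category not in mapping:
        raise ValueError(f"unrecognized sleep token: {category!r}")
    v = mapping[category]
    return np.nan if v is None else float(v)


def _binarize_series(values: pd.Series, mapping: dict[str, int | None]) -> pd.Series:
    unknown = set(values.unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unrecognized sleep tokens: {sorted(unknown)}")
    lut = {k: (np.nan if v is None else float(v)) for k, v in mapping.items()}
    return values.map(lut).astype(float)


def _full_grid(minutes: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return pd.date_range(minutes.min(), minutes.max(), freq="min")


def to_minute_grid(events: pd.DataFrame, stream: str | None = None,
                   sleep_mapping: dict[str, int | None] | None = None) -> pd.Series:
    """Aggregate one user-stream's events onto the 1-minute grid.

    Heart rate: within-minute mean.  Steps: within-minute sum.  Sleep:
    binarized, then 1 if any within-minute sample is asleep, else 0 if any
    is awake, else missing.  Minutes with no samples are explicit NaN.

    Returns a float Series indexed by a strictly increasing minute grid
    spanning the stream's first to last observed minute.
    """
    if events.empty:
        return pd.Series(dtype=float, index=pd.DatetimeIndex([], tz="UTC", freq="min"))
    stream = stream or str(events["stream"].iloc[0])
    ts = pd.to_datetime(events["timestamp"], utc=True)
    minute = ts.dt.floor("min")
    if stream == Stream.sleep.value:
        vals = _binarize_series(events["value"].astype(str), sleep_mapping or SLEEP_BINARIZATION)
        agg = vals.groupby(minute.values).max()  # any asleep -> 1; NaN only if all unknown
    else:
        vals = pd.to_numeric(events["value"])
        how = "mean" if stream == Stream.heart_rate.value else "sum"
        agg = vals.groupby(minute.values).agg(how)
    agg.index = pd.DatetimeIndex(agg.index)
    return agg.reindex(_full_grid(agg.index)).astype(float)


def clean_heart_rate(series: pd.Series, hr_floor: float = 20.0) -> tuple[pd.Series, int]:
    """Remove heart-rate values strictly below the floor (default 20 bpm).

    Returns the cleaned series and the number of values removed; removed
    slots become missing, values exactly at the floor are kept.
    """
    bad = series < hr_floor
    n_removed = int(bad.sum())
    out = series.mask(bad)
    if n_removed and out.notna().sum() == 0:
        logger.warning("clean_heart_rate: all %d values were below %.1f", n_removed, hr_floor)
    return out, n_removed


def smooth(series: pd.Series, window: int = 5, mode: str = "mean") -> pd.Series:
    """Trailing rolling statistic over the last ``window`` minutes.

    Missing values are excluded from the window; the output is missing only
    when the whole window is missing.  Partial windows at the series start
    use the available points, so ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("mean", "max"):
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    roll = series.rolling(window=window, min_periods=1)
    return roll.mean() if mode == "mean" else roll.max()


_SMOOTH_MODE = {
    Stream.heart_rate.value: "mean",
    Stream.steps.value: "mean",
    Stream.sleep.value: "max",
}


def preprocess_user(events: pd.DataFrame, params: PipelineParams | None = None,
                    sleep_mapping: dict[str, int | None] | None = None,
                    ) -> tuple[dict[str, pd.Series], dict]:
    """Harmonize one user's events: binarize -> grid -> clean -> smooth.

    Returns per-stream minute series plus a preprocessing report with
    minutes present/missing per stream and the count of removed heart-rate
    values.  Absent streams yield no series and are noted in the report.
    """
    params = params or PipelineParams()
    if events.empty:
        logger.warning("preprocess_user: user with zero events skipped")
        return {}, {"streams": {}, "absent_streams": sorted(_SMOOTH_MODE)}
    out: dict[str, pd.Series] = {}
    report: dict = {"streams": {}, "absent_streams": []}
    for stream in (Stream.heart_rate.value, Stream.steps.value, Stream.sleep.value):
        sub = events[events["stream"] == stream]
        if sub.empty:
            report["absent_streams"].append(stream)
            continue
        series = to_minute_grid(sub, stream, sleep_mapping)
        n_removed = 0
        if stream == Stream.heart_rate.value:
            series, n_removed = clean_heart_rate(series, params.hr_floor)
        series = smooth(series, params.smooth_window, _SMOOTH_MODE[stream])
        out[stream] = series
        entry = {
            "minutes_present": int(series.notna().sum()),
            "minutes_missing": int(series.isna().sum()),
        }
        if stream == Stream.heart_rate.value:
            entry["values_removed_below_floor"] = n_removed
        report["streams"][stream] = entry
    return out, report


def preprocess_events(events: pd.DataFrame, params: PipelineParams | None = None,
                      sleep_mapping: dict[str, int | None] | None = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Harmonize a whole cohort into one long minute-series table.

    Vectorized equivalent of mapping :func:`preprocess_user` over users;
    returns the long table (``user_id, stream, minute, value``) and a
    per-user report dictionary.
    """
    params = params or PipelineParams()
    frames: list[pd.DataFrame] = []
    reports: dict[str, dict] = {}
    if events.empty:
        return pd.DataFrame(columns=list(MINUTE_COLUMNS)), reports

    work = events.copy()
    work["minute"] = pd.to_datetime(work["timestamp"], utc=True).dt.floor("min")

    for stream, how in ((Stream.heart_rate.value, "mean"), (Stream.steps.value, "sum")):
        sub = work[work["stream"] == stream]
        if sub.empty:
            continue
        vals = pd.to_numeric(sub["value"])
        agg = vals.groupby([sub["user_id"], sub["minute"]]).agg(how)
        frames.append(agg.rename("value").reset_index().assign(stream=stream))

    sleep = work[work["stream"] == Stream.sleep.value]
    if not sleep.empty:
        vals = _binarize_series(sleep["value"].astype(str), sleep_mapping or SLEEP_BINARIZATION)
        agg = vals.groupby([sleep["user_id"], sleep["minute"]]).max()
        frames.append(agg.rename("value").reset_index().assign(stream=Stream.sleep.value))

    pieces: list[pd.DataFrame] = []
    for frame in frames:
        for (user, stream), grp in frame.groupby(["user_id", "stream"], sort=True):
            series = grp.set_index("minute")["value"].astype(float)
            series = series.reindex(_full_grid(series.index))
            n_removed = 0
            if stream == Stream.heart_rate.value:
                series, n_removed = clean_heart_rate(series, params.hr_floor)
            series = smooth(series, params.smooth_window, _SMOOTH_MODE[stream])
            reports.setdefault(user, {"streams": {}})["streams"][stream] = {
                "minutes_present": int(series.notna().sum()),
                "minutes_missing": int(series.isna().sum()),
                **({"values_removed_below_floor": n_removed}
                   if stream == Stream.heart_rate.value else {}),
            }
            pieces.append(
                pd.DataFrame(
                    {
                        "user_id": user,
                        "stream": stream,
                        "minute": series.index,
                        "value": series.to_numpy(),
                    }
                )
            )
    for user in events["user_id"].unique():
        streams = reports.get(user, {"streams": {}})["streams"]
        reports.setdefault(user, {"streams": {}})["absent_streams"] = sorted(
            set(_SMOOTH_MODE) - set(streams)
        )
    if not pieces:
        return pd.DataFrame(columns=list(MINUTE_COLUMNS)), reports
    minutes = pd.concat(pieces, ignore_index=True)
    minutes = minutes.sort_values(["user_id", "stream", "minute"], kind="mergesort")
    return minutes.reset_index(drop=True), reports


class MinutePreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer: raw event table -> harmonized minute table.

    Scikit-learn compatible so the harmonization step can sit in a
    :class:`sklearn.pipeline.Pipeline`; ``fit`` only validates input.
    """

    def __init__(self, params: PipelineParams | None = None,
                 sleep_mapping: dict[str, int | None] | None = None):
        self.params = params
        self.sleep_mapping = sleep_mapping

    def fit(self, X: pd.DataFrame, y: Iterable | None = None) -> "MinutePreprocessor":
        if not {"user_id", "stream", "timestamp", "value"} <= set(X.columns):
            raise ValueError("expected an event table with user_id/stream/timestamp/value")
        self.n_events_in_ = int(X.shape[0])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        minutes, reports = preprocess_events(X, self.params, self.sleep_mapping)
        self.reports_ = reports
        return minutes
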