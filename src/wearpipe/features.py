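"""Daily domain-knowledge features and user-level summary aggregation.

For each user-day (1440 aligned minute slots of heart rate, steps and
binarized sleep) twelve features are computed: the average heart rate,
total step count and number of sleep hours; mean heart rate stratified
into sleeping (binary sleep indicator 1), resting (step count 0) and
active (positive step count) categories; the active-minus-sleeping
difference; and five outlier percentages (overall heart rate, the three
strata, and steps), where an outlier is a value more than ``k`` standard
deviations (default 2) from the mean of that day's distribution of the
variable.

User-level aggregation then applies seven summary statistics (mean,
standard deviation, minimum, maximum and the 25/50/75% quartiles) to each
daily feature over a user's available days, giving 7 x 12 = 84 features
per user.  Cohort filtering removes unlabeled users and users with fewer
than ``min_days`` processed days, and restricts each remaining user to
their first ``horizon_days`` calendar days.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .params import PipelineParams, Stream

logger = logging.getLogger(__name__)

#: The twelve daily features, in canonical order.
DAILY_FEATURES = (
    "avg_hr",
    "total_steps",
    "sleep_hours",
    "sleeping_hr",
    "resting_hr",
    "active_hr",
    "active_minus_sleeping_hr",
    "outlier_pct_hr",
    "outlier_pct_sleeping_hr",
    "outlier_pct_resting_hr",
    "outlier_pct_active_hr",
    "outlier_pct_steps",
)

#: The seven user-level summary statistics, in canonical order.
SUMMARY_STATS = ("mean", "sd", "min", "max", "q25", "q50", "q75")

#: The 84 user-level feature column names, ``stat__feature``.
USER_FEATURES = tuple(f"{s}__{f}" for f in DAILY_FEATURES for s in SUMMARY_STATS)

MINUTES_PER_DAY = 1440


def split_days(minutes: pd.DataFrame, timezone: str = "UTC") -> pd.DataFrame:
    """Partition a user's minute table at local midnight into day grids.

    Returns a wide frame indexed by (date, minute-of-day) with one float
    column per stream and exactly 1440 slots per date; absent streams are
    all-missing columns.
    """
    wide = minutes.pivot_table(index="minute", columns="stream", values="value",
                               aggfunc="first")
    for stream in (Stream.heart_rate.value, Stream.steps.value, Stream.sleep.value):
        if stream not in wide.columns:
            wide[stream] = np.nan
    idx = wide.index.tz_convert(timezone)
    date = idx.date
    minute_of_day = idx.hour * 60 + idx.minute
    wide = wide.set_axis(pd.MultiIndex.from_arrays([date, minute_of_day],
                                                   names=["date", "minute_of_day"]))
    dates = pd.unique(wide.index.get_level_values("date"))
    full = pd.MultiIndex.from_product([dates, range(MINUTES_PER_DAY)],
                                      names=["date", "minute_of_day"])
    return wide.reindex(full)


def stratify_hr(hr: np.ndarray, steps: np.ndarray, sleep: np.ndarray,
                resting_awake_only: bool = False,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a day's heart-rate values into sleeping / resting / active.

    sleeping: minutes with binary sleep indicator 1; resting: minutes with
    a step count of 0 (sleep minutes included, unless ``resting_awake_only``);
    active: minutes with a positive step count.  Minutes with missing heart
    rate are excluded throughout; minutes with missing steps are excluded
    from resting and active.
    """
    has_hr = ~np.isnan(hr)
    has_steps = ~np.isnan(steps)
    sleeping = hr[has_hr & (sleep == 1)]
    resting_mask = has_hr & has_steps & (steps == 0)
    if resting_awake_only:
        resting_mask &= sleep != 1
    resting = hr[resting_mask]
    active = hr[has_hr & has_steps & (steps > 0)]
    return sleeping, resting, active


def outlier_fraction(values: np.ndarray, k: float = 2.0) -> float:
    """Percentage of values more than ``k`` sample standard deviations from the mean.

    Uses the sample (n-1) standard deviation of the supplied distribution;
    a zero (or undefined, n=1) standard deviation yields 0%.  Empty input
    propagates as missing (NaN).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.shape[0]
    if n == 0:
        return np.nan
    mean = values.mean()
    sd = values.std(ddof=1) if n > 1 else 0.0
    if sd == 0 or np.isnan(sd):
        return 0.0
    return 100.0 * float(np.count_nonzero(np.abs(values - mean) > k * sd)) / n


def compute_daily_features(hr: np.ndarray, steps: np.ndarray, sleep: np.ndarray,
                           params: PipelineParams | None = None) -> dict[str, float] | None:
    """Compute the 12-feature vector for one day grid (1440 slots per stream).

    Strata with no measurements yield missing for their features; a day
    with no data in any stream returns ``None`` (caller skips it).
    """
    params = params or PipelineParams()
    hr = np.asarray(hr, dtype=float)
    steps = np.asarray(steps, dtype=float)
    sleep = np.asarray(sleep, dtype=float)
    if np.isnan(hr).all() and np.isnan(steps).all() and np.isnan(sleep).all():
        return None
    hr_vals = hr[~np.isnan(hr)]
    step_vals = steps[~np.isnan(steps)]
    sleeping, resting, active = stratify_hr(hr, steps, sleep)
    k = params.outlier_k

    def _mean(v: np.ndarray) -> float:
        return float(v.mean()) if v.size else np.nan

    active_hr = _mean(active)
    sleeping_hr = _mean(sleeping)
    return {
        "avg_hr": _mean(hr_vals),
        "total_steps": float(step_vals.sum()) if step_vals.size else np.nan,
        "sleep_hours": (float(np.count_nonzero(sleep == 1)) / 60.0
                        if (~np.isnan(sleep)).any() else np.nan),
        "sleeping_hr": sleeping_hr,
        "resting_hr": _mean(resting),
        "active_hr": active_hr,
        "active_minus_sleeping_hr": active_hr - sleeping_hr,
        "outlier_pct_hr": outlier_fraction(hr_vals, k),
        "outlier_pct_sleeping_hr": outlier_fraction(sleeping, k),
        "outlier_pct_resting_hr": outlier_fraction(resting, k),
        "outlier_pct_active_hr": outlier_fraction(active, k),
        "outlier_pct_steps": outlier_fraction(step_vals, k),
    }


def extract_daily_features(minutes: pd.DataFrame, params: PipelineParams | None = None,
                           ) -> pd.DataFrame:
    """Daily feature table for a whole cohort: one row per user-day."""
    params = params or PipelineParams()
    rows: list[dict] = []
    for user, sub in minutes.groupby("user_id", sort=True):
        grid = split_days(sub, params.timezone)
        for date, day in grid.groupby(level="date", sort=True):
            feats = compute_daily_features(
                day[Stream.heart_rate.value].to_numpy(),
                day[Stream.steps.value].to_numpy(),
                day[Stream.sleep.value].to_numpy(),
                params,
            )
            if feats is None:
                logger.warning("user %s day %s has no data in any stream; skipped",
                               user, date)
                continue
            rows.append({"user_id": user, "date": date, **feats})
    out = pd.DataFrame(rows, columns=["user_id", "date", *DAILY_FEATURES])
    return out


def filter_cohort(daily: pd.DataFrame, labels: pd.DataFrame,
                  params: PipelineParams | None = None,
                  label_col: str = "phenotype") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion rules to a daily feature table.

    Drops users without label information, drops users with fewer than
    ``min_days`` processed days, and truncates each kept user to their
    first ``horizon_days`` calendar days.  Returns the filtered table plus
    a per-user inclusion report.
    """
    params = params or PipelineParams()
    lab = labels.set_index("user_id")[label_col]
    decisions: list[dict] = []
    kept: list[pd.DataFrame] = []
    for user, sub in daily.groupby("user_id", sort=True):
        n_days = sub.shape[0]
        if user not in lab.index or pd.isna(lab.loc[user]):
            decisions.append({"user_id": user, "included": False,
                              "reason": "unlabeled", "n_days": n_days})
            continue
        if n_days < params.min_days:
            decisions.append({"user_id": user, "included": False,
                              "reason": f"fewer_than_{params.min_days}_days",
                              "n_days": n_days})
            continue
        first = pd.Timestamp(sub["date"].min())
        cutoff = (first + pd.Timedelta(days=params.horizon_days)).date()
        trunc = sub[pd.to_datetime(sub["date"]).dt.date < cutoff]
        decisions.append({"user_id": user, "included": True, "reason": "",
                          "n_days": trunc.shape[0]})
        kept.append(trunc)
    report = pd.DataFrame(decisions, columns=["user_id", "included", "reason", "n_days"])
    if not kept:
        raise ValueError(f"empty cohort after filtering:\n{report}")
    return pd.concat(kept, ignore_index=True), report


def summarize_user(daily: pd.DataFrame) -> pd.Series:
    """Aggregate one user's daily feature vectors into the 84 summary features.

    Seven statistics per feature over available (non-missing) days;
    quartiles use linear interpolation, the standard deviation is the
    sample (n-1) form.
    """
    if daily.shape[0] < 2:
        raise ValueError("user-level summaries require at least 2 days")
    out: dict[str, float] = {}
    for feat in DAILY_FEATURES:
        v = daily[feat].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            stats = dict.fromkeys(SUMMARY_STATS, np.nan)
        else:
            stats = {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                "min": float(v.min()),
                "max": float(v.max()),
                "q25": float(np.percentile(v, 25)),
                "q50": float(np.percentile(v, 50)),
                "q75": float(np.percentile(v, 75)),
            }
        for stat in SUMMARY_STATS:
            out[f"{stat}__{feat}"] = stats[stat]
    return pd.Series(out, index=list(USER_FEATURES))


def aggregate_users(daily: pd.DataFrame) -> pd.DataFrame:
    """User feature matrix: one row per user, 84 columns plus ``n_days_used``."""
    rows = []
    for user, sub in daily.groupby("user_id", sort=True):
        s = summarize_user(sub)
        s["n_days_used"] = float(sub.shape[0])
        s.name = user
        rows.append(s)
    out = pd.DataFrame(rows)
    out.index.name = "user_id"
    return out


class DailyFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: harmonized minute table -> per-user-day 12-feature table."""

    def __init__(self, params: PipelineParams | None = None):
        self.params = params

    def fit(self, X: pd.DataFrame, y: Iterable | None = None) -> "DailyFeatureExtractor":
        if not {"user_id", "stream", "minute", "value"} <= set(X.columns):
            raise ValueError("expected a minute table with user_id/stream/minute/value")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return extract_daily_features(X, self.params)


class UserFeatureAggregator(BaseEstimator, TransformerMixin):
    """Transformer: daily feature table -> 84-column user feature matrix."""

    def fit(self, X: pd.DataFrame, y: Iterable | None = None) -> "UserFeatureAggregator":
        missing = set(DAILY_FEATURES) - set(X.columns)
        if missing:
            raise ValueError(f"daily table lacks features: {sorted(missing)}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return aggregate_users(X)
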