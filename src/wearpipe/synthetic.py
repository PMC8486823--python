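"""Synthetic multi-user wearable streams with circadian structure.

The generator emulates what a consumer wrist device records over weeks:
second-timestamped heart-rate samples following a day/night two-level
profile with white Gaussian noise, minute-level step counts concentrated in
daytime activity bouts, and categorical sleep stages forming one nightly
bout.  Phenotype-linked effects (elevated awake resting heart rate, extra
steps, longer sleep) are injected through :class:`EffectSpec`, so the whole
analysis chain can be exercised and validated for parameter recovery
without any real cohort data.

Heart rate is modelled as a piecewise-constant level (sleeping < resting <
active) plus independent Gaussian noise; no autocorrelation is simulated.
Each user owns an RNG derived from ``(seed, user index)`` so cohorts are
extensible without reshuffling earlier users.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .params import PipelineParams, Stream

MINUTES_PER_DAY = 1440

#: Sleep-stage tokens sampled inside a sleep bout, with weights.
_ASLEEP_STAGES = np.array(["light", "deep", "REM", "restless", "asleep"])
_ASLEEP_W = np.array([0.45, 0.20, 0.20, 0.05, 0.10])
#: Tokens sampled outside bouts.
_AWAKE_STAGES = np.array(["awake", "wake"])
_AWAKE_W = np.array([0.7, 0.3])


class EffectSpec(BaseModel):
    """Label-linked effects injected into phenotype-positive users."""

    rest_hr_delta: float = 0.0  # bpm added to awake resting level
    step_delta: float = 0.0  # counts/day added to mean daily steps
    sleep_delta: float = 0.0  # hours added to nightly sleep duration
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    unknown_rate: float = Field(default=0.01, ge=0.0, lt=1.0)


class UserProfile(BaseModel):
    user_id: str
    baseline_sleep_hr: float
    baseline_rest_hr: float
    baseline_active_hr: float
    sleep_onset_min: int  # minute-of-day when the nightly bout starts
    sleep_offset_min: int  # minute-of-day when it ends
    mean_daily_steps: float
    hr_noise_sd: float
    phenotype: int
    sex: int
    n_days: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "UserProfile":
        if not (self.baseline_sleep_hr < self.baseline_rest_hr < self.baseline_active_hr):
            raise ValueError("heart-rate levels must satisfy sleep < rest < active")
        return self


class Cohort(NamedTuple):
    events: pd.DataFrame
    labels: pd.DataFrame
    profiles: list[UserProfile]


def _draw_profile(rng: np.random.Generator, user_id: str, n_days: int,
                  phenotype: int, sex: int, effect: EffectSpec) -> UserProfile:
    sleep_hr = rng.normal(55.0, 3.0)
    rest_hr = sleep_hr + rng.normal(12.0, 2.0)
    active_hr = rest_hr + rng.normal(30.0, 5.0)
    # enforce the physiological ordering even in distribution tails
    rest_hr = max(rest_hr, sleep_hr + 2.0)
    active_hr = max(active_hr, rest_hr + 5.0)
    if phenotype == 1:
        rest_hr += effect.rest_hr_delta
        active_hr = max(active_hr, rest_hr + 5.0)
    onset = int(rng.normal(23 * 60, 40))
    offset = int(rng.normal(7 * 60, 40))
    if phenotype == 1:
        offset += int(round(effect.sleep_delta * 60))
    onset = int(np.clip(onset, 21 * 60, MINUTES_PER_DAY - 1))
    offset = int(np.clip(offset, 4 * 60, 11 * 60))
    steps = max(rng.normal(8000.0, 2000.0), 2000.0)
    if phenotype == 1:
        steps += effect.step_delta
    return UserProfile(
        user_id=user_id,
        baseline_sleep_hr=sleep_hr,
        baseline_rest_hr=rest_hr,
        baseline_active_hr=active_hr,
        sleep_onset_min=onset,
        sleep_offset_min=offset,
        mean_daily_steps=steps,
        hr_noise_sd=float(np.clip(rng.normal(3.0, 0.5), 1.0, None)),
        phenotype=phenotype,
        sex=sex,
        n_days=n_days,
    )


def _simulate_user(profile: UserProfile, rng: np.random.Generator,
                   start: pd.Timestamp, effect: EffectSpec) -> pd.DataFrame:
    """Emit one user's heart-rate, step and sleep events on a minute lattice.

    One sample per stream per minute; heart-rate and sleep samples carry a
    random second offset within the minute, steps sit on the minute mark.
    """
    n = profile.n_days * MINUTES_PER_DAY
    minute_of_day = np.arange(n) % MINUTES_PER_DAY
    day_index = np.arange(n) // MINUTES_PER_DAY

    # nightly sleep bout with a little day-to-day jitter
    onset_jit = profile.sleep_onset_min + rng.integers(-15, 16, profile.n_days)
    offset_jit = profile.sleep_offset_min + rng.integers(-15, 16, profile.n_days)
    asleep = (minute_of_day >= onset_jit[day_index]) | (minute_of_day < offset_jit[day_index])

    # daytime activity bouts (steps only while awake)
    steps = np.zeros(n, dtype=np.int64)
    for d in range(profile.n_days):
        n_bouts = int(rng.integers(2, 5))
        durations = rng.integers(20, 41, n_bouts)
        lam = profile.mean_daily_steps / max(int(durations.sum()), 1)
        lo = int(offset_jit[d]) + 60
        hi = int(onset_jit[d]) - 120
        starts = rng.integers(lo, max(hi, lo + 1), n_bouts)
        for s, dur in zip(starts, durations):
            a = d * MINUTES_PER_DAY + s
            b = min(a + int(dur), (d + 1) * MINUTES_PER_DAY)
            steps[a:b] = rng.poisson(lam, b - a)
    steps[asleep] = 0

    level = np.where(
        asleep,
        profile.baseline_sleep_hr,
        np.where(steps > 0, profile.baseline_active_hr, profile.baseline_rest_hr),
    )
    hr = level + rng.normal(0.0, profile.hr_noise_sd, n)
    hr = np.maximum(hr, 25.0)  # device never reports implausibly low rates

    stage = np.where(
        asleep,
        rng.choice(_ASLEEP_STAGES, n, p=_ASLEEP_W),
        rng.choice(_AWAKE_STAGES, n, p=_AWAKE_W),
    )
    if effect.unknown_rate > 0:
        stage[rng.random(n) < effect.unknown_rate] = "unknown"

    base = start.value + np.arange(n, dtype=np.int64) * 60_000_000_000
    hr_ts = base + rng.integers(0, 60, n) * 1_000_000_000
    sleep_ts = base + rng.integers(0, 60, n) * 1_000_000_000

    frames = [
        pd.DataFrame(
            {
                "user_id": profile.user_id,
                "stream": Stream.heart_rate.value,
                "timestamp": pd.to_datetime(hr_ts, utc=True),
                "value": np.round(hr, 1).astype(object),
                "unit": "bpm",
            }
        ),
        pd.DataFrame(
            {
                "user_id": profile.user_id,
                "stream": Stream.steps.value,
                "timestamp": pd.to_datetime(base, utc=True),
                "value": steps.astype(object),
                "unit": "counts/min",
            }
        ),
        pd.DataFrame(
            {
                "user_id": profile.user_id,
                "stream": Stream.sleep.value,
                "timestamp": pd.to_datetime(sleep_ts, utc=True),
                "value": stage.astype(object),
                "unit": "category",
            }
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def generate_cohort(
    n_users: int,
    effect: EffectSpec | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
    n_days: int = 30,
    start: str = "2019-01-01",
) -> Cohort:
    """Generate a labelled multi-user cohort of raw event streams.

    Phenotype labels alternate across users so both classes are always
    present; sex is drawn independently (re-balanced if degenerate).
    Identical arguments produce byte-identical output.

    Raises
    ------
    ValueError
        If ``n_users < 2`` (both phenotype classes must be represented).
    """
    if n_users < 2:
        raise ValueError("n_users must be at least 2 so both classes are represented")
    effect = effect or EffectSpec()
    params = params or PipelineParams()
    start_ts = pd.Timestamp(start, tz="UTC")

    profiles: list[UserProfile] = []
    frames: list[pd.DataFrame] = []
    sexes = np.random.default_rng([seed, 2**20]).integers(0, 2, n_users)
    if len(set(sexes.tolist())) == 1:
        sexes[0] = 1 - sexes[0]
    for i in range(n_users):
        rng = np.random.default_rng([seed, i])
        profile = _draw_profile(rng, f"u{i:04d}", n_days, i % 2, int(sexes[i]), effect)
        profiles.append(profile)
        frames.append(_simulate_user(profile, rng, start_ts, effect))

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["user_id", "stream", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    if effect.missing_rate > 0:
        events = inject_missingness(events, effect.missing_rate, seed=seed + 1_000_003)

    labels = pd.DataFrame(
        {
            "user_id": [p.user_id for p in profiles],
            "phenotype": [p.phenotype for p in profiles],
            "sex": [p.sex for p in profiles],
        }
    )
    return Cohort(events, labels, profiles)


def inject_missingness(events: pd.DataFrame, missing_rate: float, seed: int = 0) -> pd.DataFrame:
    """Drop each (user, stream, minute) group independently with the given rate.

    Emulates device wear gaps; downstream stages must represent the holes
    explicitly rather than imputing them.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0 or events.empty:
        return events.copy()
    minute = pd.to_datetime(events["timestamp"], utc=True).dt.floor("min")
    group = (
        events.assign(_minute=minute)
        .groupby(["user_id", "stream", "_minute"], sort=True)
        .ngroup()
    )
    rng = np.random.default_rng(seed)
    drop_group = rng.random(int(group.max()) + 1) < missing_rate
    kept = events.loc[~drop_group[group.to_numpy()]].reset_index(drop=True)
    return kept
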