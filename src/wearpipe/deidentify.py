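"""Future-anchored time-shift de-identification with optional value noise.

Every timestamp of a user is advanced by one fixed, strictly positive
offset drawn independently per user, so within-user relative times are
preserved exactly while absolute dates (and cross-user alignment) are
destroyed.  Numeric values may additionally receive slight zero-mean
Gaussian noise, small enough that downstream summary features are
essentially unchanged; categorical sleep stages are never perturbed.

The anchor map linking users to their offsets is identifying material and
is persisted separately from the de-identified stream, never alongside it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import Stream

logger = logging.getLogger(__name__)

#: Default value-noise scale per stream (bpm for heart rate, counts for
#: steps).  Steps default to 0 so integer counts survive unchanged.
DEFAULT_NOISE_SD = {Stream.heart_rate.value: 0.5, Stream.steps.value: 0.0}


@dataclass
class AnchorMap:
    """Per-user future offsets plus the noise configuration used."""

    offsets: dict[str, pd.Timedelta]
    value_noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "offsets_seconds": {u: int(off / pd.Timedelta(seconds=1)) for u, off in self.offsets.items()},
            "value_noise_sd": self.value_noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnchorMap":
        payload = json.loads(Path(path).read_text())
        return cls(
            offsets={u: pd.Timedelta(seconds=s) for u, s in payload["offsets_seconds"].items()},
            value_noise_sd=dict(payload["value_noise_sd"]),
            seed=int(payload["seed"]),
        )


def assign_anchors(
    user_ids: list[str],
    min_offset: pd.Timedelta = pd.Timedelta(days=365),
    max_offset: pd.Timedelta = pd.Timedelta(days=10 * 365),
    seed: int = 0,
    whole_days: bool = True,
    value_noise_sd: dict[str, float] | None = None,
) -> AnchorMap:
    """Draw one strictly positive future offset per user.

    Offsets are uniform on ``[min_offset, max_offset]``, quantized to whole
    days by default so clock-of-day structure (sleep at night) survives the
    shift, and resampled on collision so distinct users never share one.
    """
    if min_offset <= pd.Timedelta(0):
        raise ValueError("min_offset must be strictly positive")
    if max_offset < min_offset:
        raise ValueError("max_offset must be >= min_offset")
    rng = np.random.default_rng(seed)
    users = list(dict.fromkeys(user_ids))
    lo_s = int(min_offset / pd.Timedelta(seconds=1))
    hi_s = int(max_offset / pd.Timedelta(seconds=1))

    def draw() -> int:
        s = int(rng.integers(lo_s, hi_s + 1))
        if whole_days:
            s = max((s // 86400) * 86400, lo_s)
        return s

    taken: set[int] = set()
    offsets: dict[str, pd.Timedelta] = {}
    for u in users:
        s = draw()
        # degenerate ranges cannot yield distinct offsets; only resample
        # when the range has room
        attempts = 0
        while s in taken and hi_s > lo_s and attempts < 10_000:
            s = draw()
            attempts += 1
        taken.add(s)
        offsets[u] = pd.Timedelta(seconds=s)
    return AnchorMap(
        offsets=offsets,
        value_noise_sd=dict(value_noise_sd) if value_noise_sd is not None else dict(DEFAULT_NOISE_SD),
        seed=seed,
    )


def shift_timestamps(events: pd.DataFrame, anchors: AnchorMap) -> pd.DataFrame:
    """Advance every record by its user's offset.

    Within-user time differences are preserved exactly (pure addition of a
    per-user constant); cross-user relative times are not.
    """
    if events.empty:
        return events.copy()
    users = set(events["user_id"].unique())
    missing = sorted(users - set(anchors.offsets))
    if missing:
        raise KeyError(f"no anchor offset for users: {missing}")
    out = events.copy()
    offset = out["user_id"].map(anchors.offsets)
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True) + offset
    return out


def perturb_values(events: pd.DataFrame, noise_sd: dict[str, float] | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Add slight zero-mean Gaussian noise to numeric streams.

    Heart rate gets real-valued noise; step counts are re-clamped to
    non-negative integers; sleep categories pass through untouched.
    """
    noise_sd = dict(DEFAULT_NOISE_SD) if noise_sd is None else dict(noise_sd)
    for stream, sd in noise_sd.items():
        if sd < 0:
            raise ValueError(f"negative noise sd for stream {stream!r}")
    out = events.copy()
    rng = np.random.default_rng(seed)
    for stream, sd in sorted(noise_sd.items()):
        mask = (out["stream"] == stream).to_numpy()
        if sd == 0 or not mask.any():
            continue
        vals = pd.to_numeric(out.loc[mask, "value"]).to_numpy(dtype=float)
        vals = vals + rng.normal(0.0, sd, vals.shape[0])
        if stream == Stream.steps.value:
            vals = np.maximum(np.rint(vals), 0).astype(np.int64)
            out.loc[mask, "value"] = pd.Series(vals, index=out.index[mask], dtype=object)
        else:
            out.loc[mask, "value"] = pd.Series(vals, index=out.index[mask], dtype=object)
    return out


def deidentify(
    events: pd.DataFrame,
    min_offset: pd.Timedelta = pd.Timedelta(days=365),
    max_offset: pd.Timedelta = pd.Timedelta(days=10 * 365),
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, AnchorMap]:
    """Full de-identification: anchor assignment, time shift, value noise."""
    anchors = assign_anchors(
        sorted(events["user_id"].unique()),
        min_offset=min_offset,
        max_offset=max_offset,
        seed=seed,
        value_noise_sd=noise_sd,
    )
    shifted = shift_timestamps(events, anchors)
    noisy = perturb_values(shifted, anchors.value_noise_sd, seed=seed + 1)
    return noisy, anchors
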