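"""Shared domain vocabulary and the pipeline parameter registry.

Every numeric constant used downstream (cleaning threshold, smoothing
window, outlier cut-off, cohort filters, cross-validation layout) lives in
:class:`PipelineParams` so a run is fully described by one object.
"""

from __future__ import annotations

import enum

from pydantic import BaseModel, Field, model_validator


class Stream(str, enum.Enum):
    """Sensor / annotation streams carried by event records."""

    heart_rate = "heart_rate"
    steps = "steps"
    sleep = "sleep"
    label = "label"
    survey = "survey"


#: The eight sleep-stage tokens emitted by consumer wrist devices.
SLEEP_TOKENS = (
    "asleep",
    "awake",
    "wake",
    "light",
    "deep",
    "restless",
    "REM",
    "unknown",
)

#: Default binarization of the eight sleep stages: asleep-like stages map
#: to 1, awake-like to 0, and ``unknown`` to missing (``None``).
SLEEP_BINARIZATION: dict[str, int | None] = {
    "asleep": 1,
    "light": 1,
    "deep": 1,
    "restless": 1,
    "REM": 1,
    "awake": 0,
    "wake": 0,
    "unknown": None,
}

#: Canonical event-table column order for delimited-text I/O.
EVENT_COLUMNS = ("user_id", "stream", "timestamp", "value", "unit")

#: Canonical labels-table columns; unknown labels are empty cells.
LABEL_COLUMNS = ("user_id", "phenotype", "sex")


class PipelineParams(BaseModel):
    """Registry of every tunable constant in the analysis chain.

    Parameters
    ----------
    hr_floor : float
        Heart-rate values strictly below this (bpm) are treated as sensor
        artefacts and removed during cleaning.
    smooth_window : int
        Trailing rolling-window length in minutes (mean for heart rate and
        steps, max for binarized sleep).
    outlier_k : float
        Number of standard deviations beyond which a measurement counts as
        an outlier in the daily outlier-percentage features.
    min_days : int
        Users with fewer processed days than this are excluded.
    horizon_days : int
        Analysis restricted to each user's first this-many calendar days.
    cv_folds, cv_repeats : int
        Layout of the repeated k-fold cross-validation.
    l1_ratio : float
        Elastic-net mixing parameter (1 = lasso, 0 = ridge).
    regularization_strength : float
        Inverse regularization strength ``C`` of the logistic model.
    rng_seed : int
        Master seed driving every stochastic step.
    """

    hr_floor: float = Field(default=20.0, gt=0)
    smooth_window: int = Field(default=5, ge=1)
    outlier_k: float = Field(default=2.0, gt=0)
    min_days: int = Field(default=14, ge=1)
    horizon_days: int = Field(default=90, ge=1)
    cv_folds: int = Field(default=5, ge=2)
    cv_repeats: int = Field(default=10, ge=1)
    l1_ratio: float = Field(default=0.5, ge=0.0, le=1.0)
    regularization_strength: float = Field(default=1.0, gt=0)
    rng_seed: int = 0
    timezone: str = "UTC"

    @model_validator(mode="after")
    def _check(self) -> "PipelineParams":
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")
        return self
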