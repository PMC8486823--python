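"""Day-level feature-space visualization: filtering, scaling, 2-D embedding.

Each point is one user-day described by the 12 daily features.  Days with
a total step count of 0 are excluded, features are log-transformed
(signed log1p, since the active-minus-sleeping difference can be negative)
and standardized to zero mean and unit variance, then projected to two
dimensions by a pluggable neighbor-embedding backend (UMAP by default).
Per-user coordinate-wise medians summarize each individual in the plane.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .features import DAILY_FEATURES

logger = logging.getLogger(__name__)


def filter_zero_step_days(daily: pd.DataFrame) -> pd.DataFrame:
    """Drop user-days whose total step count is 0 (device not worn / idle)."""
    keep = daily["total_steps"] != 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all days have zero total steps; nothing to embed")
    if n_dropped:
        logger.info("filter_zero_step_days: dropped %d of %d days", n_dropped, len(daily))
    return daily.loc[keep].reset_index(drop=True)


def signed_log1p(x: np.ndarray) -> np.ndarray:
    """sign(x) * log(1 + |x|): order-preserving log defined on all reals."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


def log_standardize(daily: pd.DataFrame,
                    feature_cols: Iterable[str] = DAILY_FEATURES,
                    ) -> tuple[np.ndarray, list[str]]:
    """Signed-log1p transform then per-column standardization.

    Missing cells are replaced by the column mean after transform (i.e.
    standardized 0), which leaves them uninformative for the embedding
    geometry.  Constant columns become all-zero and are returned as flags.
    """
    cols = list(feature_cols)
    X = signed_log1p(daily[cols].to_numpy(dtype=float))
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    with np.errstate(invalid="ignore"):
        constant = np.nanmin(X, axis=0) == np.nanmax(X, axis=0)  # robust to sd rounding
    flagged = [cols[j] for j in np.flatnonzero(constant)]
    sd = np.where(constant | (sd == 0), 1.0, sd)
    Z = (X - mean) / sd
    Z[:, constant] = 0.0
    Z = np.where(np.isnan(Z), 0.0, Z)
    return Z, flagged


def embed_2d(matrix: np.ndarray, seed: int = 0,
             backend: Callable[[np.ndarray, int], np.ndarray] | None = None,
             ) -> np.ndarray:
    """Project rows to 2-D with a neighbor-embedding backend (UMAP default).

    The backend is a plug-in boundary: any callable ``(matrix, seed) ->
    (n, 2) array`` may replace it; the default is deterministic for a
    fixed seed and backend version.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("embedding requires at least 2 rows")
    if backend is not None:
        return np.asarray(backend(matrix, seed), dtype=float)
    import umap  # deferred: numba compilation is slow at import time

    n_neighbors = int(min(15, max(2, matrix.shape[0] - 1)))
    reducer = umap.UMAP(n_components=2, random_state=seed, n_neighbors=n_neighbors,
                        n_jobs=1)
    return np.asarray(reducer.fit_transform(matrix), dtype=float)


def user_medians(coords: pd.DataFrame) -> pd.DataFrame:
    """Coordinate-wise median point per user (the per-individual marker)."""
    return coords.groupby("user_id", sort=True)[["x", "y"]].median()


class DayEmbedding(BaseEstimator, TransformerMixin):
    """Transformer: daily feature table -> 2-D day coordinates.

    ``transform`` returns a frame with ``user_id, date, x, y``; the
    per-user medians are available as ``user_medians_`` afterwards.
    """

    def __init__(self, seed: int = 0,
                 backend: Callable[[np.ndarray, int], np.ndarray] | None = None):
        self.seed = seed
        self.backend = backend

    def fit(self, X: pd.DataFrame, y=None) -> "DayEmbedding":
        missing = set(DAILY_FEATURES) - set(X.columns)
        if missing:
            raise ValueError(f"daily table lacks features: {sorted(missing)}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered = filter_zero_step_days(X)
        Z, self.constant_features_ = log_standardize(filtered)
        xy = embed_2d(Z, seed=self.seed, backend=self.backend)
        coords = filtered[["user_id", "date"]].copy()
        coords["x"] = xy[:, 0]
        coords["y"] = xy[:, 1]
        self.user_medians_ = user_medians(coords)
        return coords
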