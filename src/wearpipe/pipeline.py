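"""End-to-end orchestration: simulate -> de-identify -> harmonize -> features
-> classify / embed, with a JSON config and a hashed run manifest.

A run is fully described by one JSON config; re-running the same config
reproduces byte-identical artifacts, which the manifest certifies by
recording the SHA-256 of every output file together with the config, the
seeds and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .classify import cross_validate
from .deidentify import deidentify
from .embed import DayEmbedding
from .features import DailyFeatureExtractor, UserFeatureAggregator, filter_cohort
from .harmonize import MinutePreprocessor, preprocess_events
from .params import PipelineParams
from .records import write_events, write_labels, write_table
from .synthetic import EffectSpec, generate_cohort

logger = logging.getLogger(__name__)


def evaluate_synthetic_cohort(n_users: int = 30, n_days: int = 60,
                              effect: EffectSpec | None = None,
                              params: PipelineParams | None = None,
                              seed: int = 0):
    """Generate a cohort and run the full chain through repeated-CV classification.

    Convenience for parameter-recovery studies: returns the
    :class:`~wearpipe.classify.CVResult` of classifying the phenotype label
    from the 84 user-level features of a synthetic cohort.
    """
    params = (params or PipelineParams()).model_copy(update={"rng_seed": seed})
    cohort = generate_cohort(n_users, effect, params, seed=seed, n_days=n_days)
    minutes, _ = preprocess_events(cohort.events, params)
    daily = DailyFeatureExtractor(params).fit_transform(minutes)
    filtered, _ = filter_cohort(daily, cohort.labels, params, label_col="phenotype")
    users = UserFeatureAggregator().fit_transform(filtered)
    y = cohort.labels.set_index("user_id")["phenotype"].loc[users.index]
    feature_cols = [c for c in users.columns if c != "n_days_used"]
    return cross_validate(users[feature_cols], y, params)


class SimulateConfig(BaseModel):
    n_users: int = 12
    n_days: int = 30
    start: str = "2019-01-01"
    effect: EffectSpec = Field(default_factory=EffectSpec)


class DeidentifyConfig(BaseModel):
    enabled: bool = True
    min_offset_days: int = 365
    max_offset_days: int = 3650
    noise_sd: dict[str, float] | None = None


class ClassifyConfig(BaseModel):
    target: str = "phenotype"  # phenotype | sex
    stratified: bool = False


class EmbedConfig(BaseModel):
    enabled: bool = True


class RunConfig(BaseModel):
    """Schema of the single JSON config driving a full run."""

    rng_seed: int  # required: every stochastic step derives from it
    params: PipelineParams = Field(default_factory=PipelineParams)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    deidentify: DeidentifyConfig = Field(default_factory=DeidentifyConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    embed: EmbedConfig = Field(default_factory=EmbedConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls.model_validate(payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order and write a hashed manifest.

    Returns the manifest dictionary.  The anchor map (identifying
    material) is written under ``<out_dir>/private/``, separate from the
    de-identified artifacts, and is excluded from the shareable manifest
    hash list.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_json(config)
    elif isinstance(config, dict):
        try:
            config = RunConfig.model_validate(config)
        except ValidationError as err:
            missing = [".".join(map(str, e["loc"])) for e in err.errors()]
            raise ValueError(f"invalid config; offending keys: {missing}") from err
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params.model_copy(update={"rng_seed": config.rng_seed})
    artifacts: dict[str, Path] = {}

    logger.info("stage simulate: %d users x %d days", config.simulate.n_users,
                config.simulate.n_days)
    cohort = generate_cohort(
        config.simulate.n_users, config.simulate.effect, params,
        seed=config.rng_seed, n_days=config.simulate.n_days,
        start=config.simulate.start,
    )
    events, labels = cohort.events, cohort.labels
    write_labels(labels, out / "labels.csv")
    artifacts["labels"] = out / "labels.csv"

    if config.deidentify.enabled:
        logger.info("stage deidentify")
        events, anchors = deidentify(
            events,
            min_offset=pd.Timedelta(days=config.deidentify.min_offset_days),
            max_offset=pd.Timedelta(days=config.deidentify.max_offset_days),
            noise_sd=config.deidentify.noise_sd,
            seed=config.rng_seed,
        )
        private = out / "private"
        private.mkdir(exist_ok=True)
        anchors.to_json(private / "anchors.json")
    write_events(events, out / "events.csv")
    artifacts["events"] = out / "events.csv"

    logger.info("stage preprocess")
    pre = MinutePreprocessor(params)
    minutes = pre.fit_transform(events)
    minutes.to_csv(out / "minutes.csv", index=False)
    (out / "preprocess_report.json").write_text(
        json.dumps(pre.reports_, indent=2, sort_keys=True, default=str)
    )
    artifacts["minutes"] = out / "minutes.csv"
    artifacts["preprocess_report"] = out / "preprocess_report.json"

    logger.info("stage features")
    daily = DailyFeatureExtractor(params).fit_transform(minutes)
    write_table(daily, out / "daily_features.csv")
    artifacts["daily_features"] = out / "daily_features.csv"

    target = config.classify.target
    filtered, inclusion = filter_cohort(daily, labels, params, label_col=target)
    write_table(inclusion, out / "cohort_report.csv")
    artifacts["cohort_report"] = out / "cohort_report.csv"
    users = UserFeatureAggregator().fit_transform(filtered)
    users.to_csv(out / "user_features.csv")
    artifacts["user_features"] = out / "user_features.csv"

    logger.info("stage classify (target=%s)", target)
    y = labels.set_index("user_id")[target].loc[users.index]
    feature_cols = [c for c in users.columns if c != "n_days_used"]
    result = cross_validate(users[feature_cols], y, params,
                            stratified=config.classify.stratified)
    result.to_json(out / "cv_result.json")
    metrics = pd.DataFrame({
        "repeat": range(params.cv_repeats),
        "auroc": result.auroc,
        "average_precision": result.average_precision,
    })
    write_table(metrics, out / "metrics.csv")
    artifacts["cv_result"] = out / "cv_result.json"
    artifacts["metrics"] = out / "metrics.csv"

    if config.embed.enabled:
        logger.info("stage embed")
        emb = DayEmbedding(seed=config.rng_seed)
        coords = emb.fit_transform(filtered)
        write_table(coords, out / "embedding.csv")
        emb.user_medians_.to_csv(out / "embedding_user_medians.csv")
        artifacts["embedding"] = out / "embedding.csv"
        artifacts["embedding_user_medians"] = out / "embedding_user_medians.csv"

    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "rng_seed": config.rng_seed,
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
        "mean_auroc": float(pd.Series(result.auroc).mean()),
        "mean_average_precision": float(pd.Series(result.average_precision).mean()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
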