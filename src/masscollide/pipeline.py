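"""Run configuration and the end-to-end analysis pipeline.

A :class:`RunConfig` bundles the experiment design, the parameters of
every model, quadrature settings, the seed and output paths.  It can be
loaded from a YAML file whose sections mirror the dataclass fields;
unknown keys are rejected so that typos fail before any computation.
:func:`run_pipeline` chains design generation, model predictions for all
five models, synthetic-participant simulation from a chosen generator,
condition summaries, inferential statistics and the NLL model comparison,
writing one CSV per stage plus diagnostic figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from .alternatives import (
    HeuristicParams,
    ImportanceSampler,
    LogisticWeights,
    fillin_predict,
    gp_predict,
    logistic_predict,
)
from .observer import GridPosterior, GridSettings, ObserverParams
from .physics import ConfigError, ExperimentDesign
from .simulate import DEFAULT_GROUP_SIZES, simulate_dataset, write_dataset
from .stats import compare_models, e_difference, jzs_bayes_factor, one_sample_t, summarize

logger = logging.getLogger("masscollide")

MODEL_NAMES = ("noisy-newton", "gp", "gp-fillin", "logistic", "importance", "chance")

__all__ = ["RunConfig", "MODEL_NAMES", "build_model", "predictions_table", "run_pipeline"]


@dataclass(frozen=True)
class ImportanceSettings:
    """Sample sizes of the exemplar approximation."""

    n_samples: int = 50
    n_participants: int = 500


@dataclass(frozen=True)
class SimulateSettings:
    """Which model generates the synthetic participants, and how many."""

    model: str = "noisy-newton"
    n_participants: int = sum(DEFAULT_GROUP_SIZES)

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ConfigError(
                f"unknown model {self.model!r}; choose from {MODEL_NAMES}"
            )
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    observer: ObserverParams = field(default_factory=ObserverParams)
    heuristic: HeuristicParams = field(default_factory=HeuristicParams)
    logistic: LogisticWeights = field(default_factory=LogisticWeights)
    importance: ImportanceSettings = field(default_factory=ImportanceSettings)
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    grid: GridSettings = field(default_factory=GridSettings)
    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "INFO"

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed), design=replace(self.design, seed=int(seed)))

    def describe(self) -> str:
        return json.dumps(_to_plain(self), indent=2, sort_keys=True)


def _build_section(cls, data: Any, where: str):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"config section {where!r} must be a mapping")
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in config section {where!r}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config section {where!r}: {exc}") from exc


_SECTIONS = {
    "design": ExperimentDesign,
    "observer": ObserverParams,
    "heuristic": HeuristicParams,
    "logistic": LogisticWeights,
    "importance": ImportanceSettings,
    "simulate": SimulateSettings,
    "grid": GridSettings,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path=None, mapping: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or a plain mapping.

    Unknown keys anywhere in the document raise :class:`ConfigError`.
    """
    if mapping is None:
        text = Path(path).read_text(encoding="utf-8")
        mapping = yaml.safe_load(text) or {}
    if not isinstance(mapping, dict):
        raise ConfigError("config document must be a mapping")
    scalar_fields = {"seed", "out_dir", "verbosity"}
    unknown = set(mapping) - set(_SECTIONS) - scalar_fields
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        name: _build_section(cls, mapping.get(name), name)
        for name, cls in _SECTIONS.items()
    }
    for name in scalar_fields:
        if name in mapping:
            kwargs[name] = mapping[name]
    config = RunConfig(**kwargs)
    return config.with_seed(config.seed)


def build_model(name: str, config: RunConfig | None = None) -> Callable:
    """Observation -> probability predictor for a named model."""
    config = config or RunConfig()
    if name == "noisy-newton":
        engine = GridPosterior(config.observer, config.grid)
        return engine.posterior
    if name == "gp":
        return lambda obs: gp_predict(obs, config.heuristic)
    if name == "gp-fillin":
        return lambda obs: fillin_predict(obs, config.heuristic, config.design)
    if name == "logistic":
        return lambda obs: logistic_predict(obs, config.logistic)
    if name == "importance":
        sampler = ImportanceSampler(
            config.observer,
            n_samples=config.importance.n_samples,
            n_participants=config.importance.n_participants,
            seed=config.seed,
        )
        return sampler.predict
    if name == "chance":
        return lambda obs: 0.5
    raise ConfigError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def predictions_table(
    config: RunConfig, models: tuple[str, ...] = MODEL_NAMES[:5]
) -> pd.DataFrame:
    """Cell-level predictions CSV schema: model, mass_ratio_r, e, occlusion, p_motor.

    Each entry is the model's response probability averaged over the
    design's initial-velocity grid for one signed condition cell.
    """
    from .observer import cell_observations

    rows = []
    for name in models:
        predictor = build_model(name, config)
        for cell in config.design.prediction_cells():
            obs = cell_observations(config.design, cell)
            p = float(np.mean([predictor(o) for o in obs]))
            rows.append(
                {
                    "model": name,
                    "mass_ratio_r": cell[0],
                    "e": cell[1],
                    "occlusion": cell[2],
                    "p_motor": p,
                }
            )
    return pd.DataFrame(rows)


def _analysis_tables(dataset: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition summary plus accuracy / e-difference tests per occlusion."""
    summary = summarize(dataset)
    tests = []
    for occ in sorted(dataset["occlusion"].unique()):
        per = summary.per_participant
        acc = (
            per[per["occlusion"] == occ]
            .groupby("participant_id")["accuracy"]
            .mean()
            .to_numpy()
        )
        t, df, p = one_sample_t(acc, 0.5)
        tests.append(
            {
                "occlusion": occ,
                "measure": "accuracy_vs_chance",
                "mean": float(np.mean(acc)),
                "t": t,
                "df": df,
                "p": p,
                "bf10": jzs_bayes_factor(t, df + 1),
            }
        )
        diffs = e_difference(summary, occ).to_numpy()
        t, df, p = one_sample_t(diffs, 0.0)
        tests.append(
            {
                "occlusion": occ,
                "measure": "e_difference_vs_zero",
                "mean": float(np.mean(diffs)),
                "t": t,
                "df": df,
                "p": p,
                "bf10": jzs_bayes_factor(t, df + 1),
            }
        )
    return summary.cells, pd.DataFrame(tests)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Stages: model predictions for every cell -> synthetic dataset from the
    configured generating model -> condition summary and tests -> NLL
    model comparison -> prediction figures.  Byte-reproducible given the
    seed.  Returns the paths of the written artifacts.
    """
    from .plotting import plot_predictions

    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    logger.info("resolved config:\n%s", config.describe())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    preds = stage("predict", lambda: predictions_table(config))
    artifacts["predictions"] = out / "predictions.csv"
    preds.to_csv(artifacts["predictions"], index=False)

    gen_name = config.simulate.model
    dataset = stage(
        "simulate",
        lambda: simulate_dataset(
            config.design,
            build_model(gen_name, config),
            n_participants=config.simulate.n_participants,
            seed=config.seed,
            model_name=gen_name,
        ),
    )
    artifacts["dataset"] = out / "dataset.csv"
    write_dataset(dataset, artifacts["dataset"])

    cells, tests = stage("analyze", lambda: _analysis_tables(dataset))
    artifacts["summary"] = out / "summary.csv"
    cells.to_csv(artifacts["summary"], index=False)
    artifacts["tests"] = out / "tests.csv"
    tests.to_csv(artifacts["tests"], index=False)

    models = {name: build_model(name, config) for name in MODEL_NAMES}
    comparison = stage("compare", lambda: compare_models(dataset, models))
    artifacts["comparison"] = out / "comparison.csv"
    comparison.to_csv(artifacts["comparison"], index=False)

    figures = stage("plot", lambda: plot_predictions(preds, out))
    for path in figures:
        artifacts[Path(path).stem] = Path(path)
    logger.info("pipeline artifacts: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts
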