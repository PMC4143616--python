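"""Synthetic participant response datasets.

The human responses for this task are not public, so every downstream
stage is exercised on probability-matched synthetic participants: each
participant receives a fresh randomized trial sequence from the experiment
design, and each binary response (motor vs projectile heavier) is a
Bernoulli draw with success probability given by any of the implemented
models.  One global seed drives per-participant substreams, so adding
participants never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .physics import (
    OCCLUSIONS,
    SIDES,
    TRIAL_COLUMNS,
    ExperimentDesign,
    VisibleObservation,
    _participant_rng,
    generate_design,
    trial_observation,
    trials_to_frame,
)

__all__ = ["DATASET_COLUMNS", "simulate_dataset", "write_dataset", "read_dataset"]


class ModelContractError(ValueError):
    """A model returned a probability outside [0, 1]."""


DATASET_COLUMNS = TRIAL_COLUMNS + (
    "generating_model",
    "p_motor_true",
    "response",
    "correct",
)

#: Group sizes of the two occlusion-display groups in the emulated study
#: (object-change and background-change displays; one generative process).
DEFAULT_GROUP_SIZES = (20, 22)

ModelFn = Callable[[VisibleObservation], float]


def _as_predictor(model) -> ModelFn:
    if callable(model):
        return model
    if hasattr(model, "predict"):
        return model.predict
    raise TypeError("model must be a callable obs -> probability or expose .predict")


def simulate_dataset(
    design: ExperimentDesign,
    model,
    n_participants: int = sum(DEFAULT_GROUP_SIZES),
    seed: int = 0,
    model_name: str = "model",
    participant_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate probability-matched responses for ``n_participants``.

    Each participant gets an independently randomized trial sequence (via
    :func:`masscollide.physics.generate_design`) and per-trial Bernoulli
    responses with success probability ``model(observation)``.  Model
    probabilities are cached per unique observation, so deterministic
    models over the discrete design grid are evaluated only once per
    distinct stimulus.  Fully deterministic given ``seed``.
    """
    predictor = _as_predictor(model)
    design = replace(design, seed=seed)
    cache: dict[tuple, float] = {}
    records = []
    for i in range(n_participants):
        pid = f"{participant_prefix}{i:03d}"
        trials = generate_design(design, pid)
        rng = _participant_rng(seed, pid, "response")
        for trial in trials:
            obs = trial_observation(trial)
            key = (obs.u_obs, obs.va_obs, obs.vb_obs)
            if key not in cache:
                p = float(predictor(obs))
                if not 0.0 <= p <= 1.0:
                    raise ModelContractError(
                        f"model returned probability {p!r} outside [0, 1] "
                        f"for observation {obs}"
                    )
                cache[key] = p
            p = cache[key]
            response = "motor" if rng.random() < p else "projectile"
            correct = (response == "motor") == (trial.mass_ratio_r > 1.0)
            rec = {col: getattr(trial, col) for col in TRIAL_COLUMNS}
            rec.update(
                generating_model=model_name,
                p_motor_true=p,
                response=response,
                correct=correct,
            )
            records.append(rec)
    return pd.DataFrame(records, columns=list(DATASET_COLUMNS))


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a response dataset as UTF-8 CSV ('.' decimal, header row)."""
    dataset.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a response dataset CSV.

    Raises ``ValueError`` naming the first offending row on malformed
    content: unknown occlusion/side/response labels or probabilities
    outside [0, 1].  A header-only file yields an empty dataset.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(DATASET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    if len(frame) == 0:
        return frame.reindex(columns=list(DATASET_COLUMNS))

    def _check(column: str, valid) -> None:
        bad = ~frame[column].isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {row}: invalid {column} value {frame[column].iloc[row]!r}"
            )

    _check("occlusion", OCCLUSIONS)
    _check("heavier_side", SIDES)
    _check("response", ("motor", "projectile"))
    p = pd.to_numeric(frame["p_motor_true"], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"row {row}: p_motor_true {frame['p_motor_true'].iloc[row]!r} "
            "is not a probability"
        )
    for col in ("is_practice", "correct"):
        if frame[col].dtype != bool:
            mapped = frame[col].map({True: True, False: False, "True": True, "False": False})
            if mapped.isna().any():
                row = int(np.flatnonzero(mapped.isna())[0])
                raise ValueError(f"row {row}: {col} must be boolean")
            frame[col] = mapped.astype(bool)
    return frame[list(DATASET_COLUMNS)]
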