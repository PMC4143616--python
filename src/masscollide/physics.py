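"""Newtonian kinematics of one-dimensional two-body collisions and the
occlusion-experiment design.

The task being modelled: a *motor* object slides rightward with initial
velocity ``u_a`` (cm/s, rightward positive) into an initially stationary
*projectile* object.  After contact the two objects separate with final
velocities ``v_a`` (motor) and ``v_b`` (projectile) fully determined by the
mass ratio ``r = m_a / m_b`` and the coefficient of restitution ``e``::

    v_a = u_a * (r - e) / (r + 1)
    v_b = u_a * r * (1 + e) / (r + 1)

Conservation of momentum yields the normative rule for judging which object
is heavier from the velocities alone:  ``m_a > m_b``  iff  ``v_a + v_b >
u_a``.  Algebraically ``v_a + v_b - u_a = u_a (r - 1)(1 + e) / (r + 1)``,
so for ``u_a > 0`` the rule agrees exactly with ``sign(r - 1)``.  The motor
object ricochets (``v_a < 0``) exactly when ``r < e``.

An experiment session crosses mass ratio x restitution x occlusion
(which object, if either, becomes invisible at contact) into condition
cells, with the initial velocity drawn per trial from a discrete grid and
the heavier side assigned by a fair coin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OCCLUSIONS",
    "SIDES",
    "TIE_TOL",
    "CollisionTrial",
    "VisibleObservation",
    "ExperimentDesign",
    "final_velocities",
    "heavier_motor_normative",
    "is_ricochet",
    "generate_design",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "trial_observation",
]

#: Valid occlusion labels: which object disappears at contact.
OCCLUSIONS = ("none", "motor", "projectile")

#: Which side carries the heavier object (the motor object is always left).
SIDES = ("left", "right")

#: Absolute tolerance (cm/s) for velocity-sum ties in the normative rule.
TIE_TOL = 1e-9


class ConfigError(ValueError):
    """Invalid experiment-design or run configuration."""


def final_velocities(u_a: float, r: float, e: float) -> tuple[float, float]:
    """Final velocities of motor and projectile objects after the collision.

    Parameters
    ----------
    u_a : float
        Initial velocity of the motor object, cm/s (rightward positive).
    r : float
        Mass ratio ``m_a / m_b`` of motor to projectile object; must be > 0.
    e : float
        Coefficient of restitution in [0, 1] (1 elastic, 0 perfectly
        inelastic).

    Returns
    -------
    (v_a, v_b) : tuple of float
        Final velocities of the motor and projectile objects, cm/s.  They
        satisfy momentum conservation ``r*u_a == r*v_a + v_b`` and the
        restitution identity ``v_b - v_a == e*u_a``.
    """
    u_a = float(u_a)
    if not np.isfinite(u_a):
        raise ValueError(f"u_a must be finite, got {u_a!r}")
    if not (r > 0):
        raise ValueError(f"mass ratio r must be positive, got {r!r}")
    if not (0.0 <= e <= 1.0):
        raise ValueError(f"coefficient of restitution must lie in [0, 1], got {e!r}")
    v_a = u_a * (r - e) / (r + 1.0)
    v_b = u_a * r * (1.0 + e) / (r + 1.0)
    return v_a, v_b


def heavier_motor_normative(u_a: float, v_a: float, v_b: float) -> str:
    """Normative mass judgment from momentum conservation.

    Returns ``"motor"`` if ``v_a + v_b > u_a`` (motor object heavier),
    ``"projectile"`` if the sum is smaller, and ``"tie"`` if the two sides
    agree within :data:`TIE_TOL`.  All three velocities must be observed:
    the rule gives no answer when a final velocity is missing.
    """
    if u_a is None or v_a is None or v_b is None:
        raise ValueError("normative rule requires all of u_a, v_a, v_b observed")
    diff = (v_a + v_b) - u_a
    if abs(diff) <= TIE_TOL:
        return "tie"
    return "motor" if diff > 0 else "projectile"


def is_ricochet(v_a: float) -> bool:
    """True iff the motor object reversed direction (``v_a < 0``).

    For noise-free collision trials this holds exactly when ``r < e``.
    """
    if v_a is None:
        raise ValueError("ricochet judgment requires the motor final velocity")
    return v_a < 0


@dataclass(frozen=True)
class CollisionTrial:
    """One collision event with condition labels and occlusion mask.

    The occlusion label only masks *visibility* (see
    :func:`trial_observation`); the masked velocity is still stored.
    """

    participant_id: str
    trial_index: int
    is_practice: bool
    mass_ratio_r: float  # r = m_a / m_b, motor over projectile
    e: float
    occlusion: str
    heavier_side: str
    u_a: float
    v_a: float
    v_b: float

    def __post_init__(self) -> None:
        if self.occlusion not in OCCLUSIONS:
            raise ValueError(f"unknown occlusion label {self.occlusion!r}")
        if self.heavier_side not in SIDES:
            raise ValueError(f"unknown heavier_side label {self.heavier_side!r}")

    @property
    def observation(self) -> "VisibleObservation":
        return trial_observation(self)


@dataclass(frozen=True)
class VisibleObservation:
    """Velocities available to the observer on one trial.

    A ``None`` entry means that channel was occluded (or otherwise not
    shown).  In the experiment the initial velocity is always visible and
    at most one final velocity is missing.
    """

    u_obs: float | None
    va_obs: float | None
    vb_obs: float | None

    def visible_channels(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, v in (("u", self.u_obs), ("va", self.va_obs), ("vb", self.vb_obs))
            if v is not None
        )


def trial_observation(trial: CollisionTrial) -> VisibleObservation:
    """Mask the occluded channel of a trial; the stored velocities remain."""
    return VisibleObservation(
        u_obs=trial.u_a,
        va_obs=None if trial.occlusion == "motor" else trial.v_a,
        vb_obs=None if trial.occlusion == "projectile" else trial.v_b,
    )


def _default_velocity_grid() -> tuple[float, ...]:
    # 1.91 to 4.45 cm/s in steps of 0.13 does not close on the end point;
    # keep the stated start and step: 20 values, max 4.38.
    return tuple(round(1.91 + 0.13 * k, 2) for k in range(20))


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of the occlusion experiment.

    Defaults give the 12-cell design: heavier/lighter mass ratios
    {1.25, 3.0} x restitutions {1.0, 0.1} x occlusions {none, motor,
    projectile}, 15 test replications per cell plus one practice trial per
    cell, i.e. 192 trials per participant.  The heavier object is placed
    left or right by a fair coin independently per trial, so the signed
    motor/projectile ratio ``r`` takes values ratio or 1/ratio.
    """

    mass_ratios: tuple[float, ...] = (1.25, 3.0)
    restitutions: tuple[float, ...] = (1.0, 0.1)
    occlusions: tuple[str, ...] = OCCLUSIONS
    velocity_grid: tuple[float, ...] = field(default_factory=_default_velocity_grid)
    replications_per_cell: int = 15
    practice_per_cell: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mass_ratios", "restitutions", "occlusions", "velocity_grid"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"design factor {name!r} must be non-empty")
        for occ in self.occlusions:
            if occ not in OCCLUSIONS:
                raise ConfigError(f"unknown occlusion label {occ!r}")
        for ratio in self.mass_ratios:
            if not ratio > 0:
                raise ConfigError(f"mass ratio must be positive, got {ratio!r}")
        for e in self.restitutions:
            if not 0.0 <= e <= 1.0:
                raise ConfigError(f"restitution must lie in [0, 1], got {e!r}")
        if any(not u > 0 for u in self.velocity_grid):
            raise ConfigError("velocity grid must be strictly positive (rightward)")
        if self.replications_per_cell < 1 or self.practice_per_cell < 0:
            raise ConfigError("replication counts must be positive")

    def condition_cells(self) -> list[tuple[float, float, str]]:
        """The (heavier/lighter ratio, e, occlusion) cells; 12 by default."""
        return [
            (ratio, e, occ)
            for ratio in self.mass_ratios
            for e in self.restitutions
            for occ in self.occlusions
        ]

    def prediction_cells(self) -> list[tuple[float, float, str]]:
        """Signed-ratio cells (r = m_a/m_b in {1/ratio, ratio}); 24 by default.

        These are the cells on which model predictions are reported: each
        condition cell splits into heavier-left (r = ratio) and
        heavier-right (r = 1/ratio).
        """
        signed: list[float] = []
        for ratio in self.mass_ratios:
            for r in (1.0 / ratio, ratio):
                if r not in signed:
                    signed.append(r)
        return [
            (r, e, occ)
            for r in sorted(signed)
            for e in self.restitutions
            for occ in self.occlusions
        ]

    @property
    def trials_per_participant(self) -> int:
        n_cells = len(self.condition_cells())
        return n_cells * (self.practice_per_cell + self.replications_per_cell)


def _participant_rng(seed: int, participant_id: str, stream: str) -> np.random.Generator:
    """Deterministic per-participant random stream.

    The participant label is hashed so that adding participants never
    perturbs the streams of existing ones.
    """
    digest = hashlib.blake2b(
        f"{stream}:{participant_id}".encode("utf-8"), digest_size=8
    ).digest()
    key = int.from_bytes(digest[:4], "little")  # < 2**32
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def generate_design(
    design: ExperimentDesign, participant_id: str = "p000"
) -> list[CollisionTrial]:
    """Generate one participant's randomized trial sequence.

    Practice trials (one per condition cell by default, flagged
    ``is_practice``) come first in randomized order, followed by the test
    trials (``replications_per_cell`` per cell) in fully randomized order.
    Per trial the initial velocity is drawn uniformly from the velocity
    grid, the heavier side by a fair coin, and the final velocities follow
    from the collision kinematics.  Deterministic given ``(design.seed,
    participant_id)``.
    """
    rng = _participant_rng(design.seed, participant_id, "design")
    cells = design.condition_cells()

    def make_block(reps: int, is_practice: bool, start: int) -> list[CollisionTrial]:
        block_cells = [cell for cell in cells for _ in range(reps)]
        order = rng.permutation(len(block_cells))
        trials = []
        for i, j in enumerate(order):
            ratio, e, occ = block_cells[j]
            u_a = float(rng.choice(design.velocity_grid))
            heavier_side = "left" if rng.random() < 0.5 else "right"
            r = ratio if heavier_side == "left" else 1.0 / ratio
            v_a, v_b = final_velocities(u_a, r, e)
            trials.append(
                CollisionTrial(
                    participant_id=participant_id,
                    trial_index=start + i,
                    is_practice=is_practice,
                    mass_ratio_r=r,
                    e=e,
                    occlusion=occ,
                    heavier_side=heavier_side,
                    u_a=u_a,
                    v_a=v_a,
                    v_b=v_b,
                )
            )
        return trials

    practice = make_block(design.practice_per_cell, True, 0)
    test = make_block(design.replications_per_cell, False, len(practice))
    return practice + test


TRIAL_COLUMNS = (
    "participant_id",
    "trial_index",
    "is_practice",
    "mass_ratio_r",
    "e",
    "occlusion",
    "heavier_side",
    "u_a",
    "v_a",
    "v_b",
)


def trials_to_frame(trials: Iterable[CollisionTrial]) -> pd.DataFrame:
    """Tabulate trials, one row per trial, in the trial-table CSV schema."""
    rows = [
        {col: getattr(t, col) for col in TRIAL_COLUMNS} for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def frame_to_trials(frame: pd.DataFrame) -> list[CollisionTrial]:
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = []
    for idx, row in frame.iterrows():
        try:
            trials.append(
                CollisionTrial(
                    participant_id=str(row["participant_id"]),
                    trial_index=int(row["trial_index"]),
                    is_practice=bool(row["is_practice"]),
                    mass_ratio_r=float(row["mass_ratio_r"]),
                    e=float(row["e"]),
                    occlusion=str(row["occlusion"]),
                    heavier_side=str(row["heavier_side"]),
                    u_a=float(row["u_a"]),
                    v_a=float(row["v_a"]),
                    v_b=float(row["v_b"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed trial row {idx}: {exc}") from exc
    return trials


def write_trials(trials: Iterable[CollisionTrial] | pd.DataFrame, path) -> None:
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    frame.to_csv(path, index=False)


def read_trials(path) -> list[CollisionTrial]:
    # round_trip parsing keeps the velocities bit-exact across a CSV cycle
    return frame_to_trials(pd.read_csv(path, float_precision="round_trip"))
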