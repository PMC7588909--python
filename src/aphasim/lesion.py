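"""In-silico precision lesions on the sensory likelihood.

The lesion lowers the precision hyperparameter ω of targeted likelihood
columns: each targeted column ``c`` is replaced by ``normalise(exp(ω·ln c))``.
ω = 1 leaves the stored representation untouched; ω → 0 drives targeted
columns to the uniform distribution.  Only the agent's generative model is
lesioned — the environment always emits from the intact process — so any
behavioural difference under matched seeds is attributable to belief
updating alone.

A :class:`LesionTarget` names the affected language and the modalities whose
columns are flattened.  A column is targeted when its heard-language index
(in its epoch-1 role: processing what is heard) or its target-language index
(epoch-2 role: predicting the consequences of speaking) equals the affected
language.  The committed default targets the auditory-stream modalities
(audition, language) together with the evaluative feedback channel; narrower
variants remain selectable for lesion-locus studies.

A :class:`PrecisionSchedule` assigns one (ω, target) pair per simulated day.
The default nine-day schedule alternates the affected language daily and
steps ω through 0.1, 0.1, 0.1, 0.1, 0.25, 0.25, 0.5, 0.5, 1 — a staircase
recovery reaching full precision on the final day.  A "slow" preset stretches
the same trajectory over a longer horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .engine import GenerativeModel, InvalidInputError
from .taskmodel import LANGUAGES

__all__ = [
    "DEFAULT_TARGET_MODALITIES",
    "DEFAULT_OMEGA_TRAJECTORY",
    "LesionTarget",
    "ScheduleEntry",
    "PrecisionSchedule",
    "apply_precision",
    "make_schedule",
    "lesion_model",
]

DEFAULT_TARGET_MODALITIES = ("audition", "language", "feedback")
DEFAULT_OMEGA_TRAJECTORY = (0.1, 0.1, 0.1, 0.1, 0.25, 0.25, 0.5, 0.5, 1.0)


@dataclass(frozen=True)
class LesionTarget:
    """Which likelihood columns a lesion flattens.

    ``affected_language`` is "L1" or "L2"; ``modalities`` lists the outcome
    channels whose columns are touched.
    """

    affected_language: str
    modalities: tuple[str, ...] = DEFAULT_TARGET_MODALITIES

    def __post_init__(self):
        if self.affected_language not in LANGUAGES:
            raise InvalidInputError(f"unknown language {self.affected_language!r}")

    def column_mask(self, model: GenerativeModel) -> np.ndarray:
        """Boolean mask over joint states: True where columns are targeted.

        Epoch-1 columns are targeted by their heard-language index, epoch-2
        columns by their target-language index.
        """
        for m in self.modalities:
            model.modality(m)  # existence check
        shape = model.state_shape
        hi = model.factor_index("heard")
        ti = model.factor_index("target")
        ei = model.factor_index("epoch")
        aff = LANGUAGES.index(self.affected_language)
        grids = np.indices(shape)
        return ((grids[ei] == 0) & (grids[hi] == aff)) | (
            (grids[ei] == 1) & (grids[ti] == aff)
        )


@dataclass(frozen=True)
class ScheduleEntry:
    day: int
    omega: float
    target: LesionTarget


@dataclass(frozen=True)
class PrecisionSchedule:
    """Day-indexed precision values and lesion targets (days contiguous from 1)."""

    entries: tuple[ScheduleEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise InvalidInputError("schedule must contain at least one day")
        for i, e in enumerate(self.entries):
            if e.day != i + 1:
                raise InvalidInputError("schedule days must be contiguous from 1")
            if not (e.omega > 0):
                raise InvalidInputError(f"omega must be positive (day {e.day})")
            if e.omega > 1:
                warnings.warn(f"omega {e.omega} outside (0, 1] on day {e.day}", stacklevel=2)

    @property
    def n_days(self) -> int:
        return len(self.entries)

    def entry(self, day: int) -> ScheduleEntry:
        if not (1 <= day <= len(self.entries)):
            raise InvalidInputError(f"day {day} outside schedule")
        return self.entries[day - 1]

    @staticmethod
    def intact(n_days: int, modalities: tuple[str, ...] = DEFAULT_TARGET_MODALITIES) -> "PrecisionSchedule":
        """An all-ω=1 (control) schedule."""
        return PrecisionSchedule(
            tuple(
                ScheduleEntry(d, 1.0, LesionTarget("L1", modalities))
                for d in range(1, n_days + 1)
            )
        )


def apply_precision(
    likelihoods: Mapping[str, np.ndarray],
    omega: float,
    target: LesionTarget,
    model: GenerativeModel,
) -> dict[str, np.ndarray]:
    """Flatten targeted likelihood columns by raising them to the power ω.

    For each targeted column ``c``: ``c' = normalise(exp(ω · ln c))`` (i.e.
    ``c**ω`` renormalised — a monotone, order-preserving transform of the
    column).  Untargeted columns and modalities pass through unchanged.
    ω = 1 returns the input bitwise.
    """
    if not (np.isfinite(omega) and omega > 0):
        raise InvalidInputError("omega must be a positive real")
    out = {name: A.copy() for name, A in likelihoods.items()}
    if omega == 1.0:
        return out
    mask = target.column_mask(model)
    for name in target.modalities:
        A = out[name]
        cols = A[:, mask]  # (n_outcomes, n_targeted)
        flat = np.exp(omega * np.log(cols))
        A[:, mask] = flat / flat.sum(axis=0, keepdims=True)
    return out


def make_schedule(config: Mapping | None = None) -> PrecisionSchedule:
    """Build a precision schedule from a configuration mapping.

    Keys (all optional when ``config`` is None is not allowed — an empty
    config is an error):

    * ``days`` — number of days (default 9);
    * ``omegas`` — per-day ω trajectory (default the committed staircase);
    * ``first_affected`` — language lesioned on day 1 (default "L1";
      alternates daily thereafter);
    * ``modalities`` — targeted modalities;
    * ``preset`` — "default" or "slow" (the same staircase stretched over
      three-day plateaus, emulating recovery at a slower timescale).
    """
    if config is None or (isinstance(config, Mapping) and not config):
        raise InvalidInputError("schedule config must not be empty")
    preset = config.get("preset", "default")
    modalities = tuple(config.get("modalities", DEFAULT_TARGET_MODALITIES))
    first = config.get("first_affected", "L1")
    if first not in LANGUAGES:
        raise InvalidInputError(f"unknown language {first!r}")
    if preset == "slow":
        omegas = tuple(w for w in DEFAULT_OMEGA_TRAJECTORY for _ in range(3))
    elif preset == "default":
        omegas = tuple(config.get("omegas", DEFAULT_OMEGA_TRAJECTORY))
    else:
        raise InvalidInputError(f"unknown preset {preset!r}")
    days = int(config.get("days", len(omegas)))
    if days < 1:
        raise InvalidInputError("schedule must cover at least one day")
    if len(omegas) < days:
        omegas = omegas + (omegas[-1],) * (days - len(omegas))
    other = {"L1": "L2", "L2": "L1"}
    entries = []
    aff = first
    for d in range(1, days + 1):
        entries.append(ScheduleEntry(d, float(omegas[d - 1]), LesionTarget(aff, modalities)))
        aff = other[aff]
    return PrecisionSchedule(tuple(entries))


def lesion_model(model: GenerativeModel, schedule: PrecisionSchedule, day: int) -> GenerativeModel:
    """The agent model with the given day's lesion applied (pure function)."""
    e = schedule.entry(day)
    out = model.copy()
    out.likelihoods = apply_precision(model.likelihoods, e.omega, e.target, model)
    return out
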