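"""Domain types for game-based attention-training sessions.

A treatment program is a sequence of game sessions. Each session presents
``n_trials`` trials (default 10), each limited to ``trial_limit`` seconds
(default 60). A trial ends one of four ways:

* ``correct``   — the patient selected the target stimulus (carries a
  response time, the CRT);
* ``commission``— the patient selected the non-target stimulus (carries a
  response time; indexes impulsivity);
* ``omission``  — the timer expired with no response (no response time;
  indexes inattention);
* ``quit``      — the patient ended the game before completing the session.

A quit is recorded as its own trial record and must be the last record of a
session; every trial slot after it counts as an uncompleted try (K).
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Outcome",
    "Visibility",
    "GameType",
    "PatientProfile",
    "DoctorProfile",
    "ObjectSpec",
    "LevelSpec",
    "GameSpec",
    "SessionConfig",
    "TrialRecord",
    "SessionLog",
    "TreatmentProgram",
    "validate_session_log",
]


class Outcome(str, enum.Enum):
    """How a single trial ended."""

    CORRECT = "correct"
    COMMISSION = "commission"
    OMISSION = "omission"
    QUIT = "quit"


class Visibility(str, enum.Enum):
    SIMULTANEOUS = "simultaneous"
    SEQUENTIAL = "sequential"


class GameType(str, enum.Enum):
    DRAG_AND_DROP = "drag_and_drop"
    MULTIPLE_CHOICE = "multiple_choice"


class PatientProfile(BaseModel):
    """A patient enrolled in the training program."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    level: int = Field(ge=1, description="current treatment level")
    performance_index: float = Field(ge=0.0, le=1.0)
    preferences: frozenset[str] = frozenset()


class DoctorProfile(BaseModel):
    """The supervising therapist."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    experience: int = Field(ge=0, description="ordinal experience level")
    involvement: int = Field(ge=0, description="ordinal involvement level")


class ObjectSpec(BaseModel):
    """One stimulus object shown during a trial."""

    model_config = ConfigDict(frozen=True)

    shape: str
    size: float = Field(gt=0.0)
    random_location: bool = True
    visibility: Visibility = Visibility.SIMULTANEOUS


class LevelSpec(BaseModel):
    """A difficulty level: its stimuli, time budget and guidance effects.

    ``max_time`` is carried as configuration metadata; the per-trial limit
    that scoring uses lives on :class:`SessionConfig`.
    """

    model_config = ConfigDict(frozen=True)

    objects: tuple[ObjectSpec, ...] = Field(min_length=2)
    max_time: float = Field(gt=0.0, description="seconds")
    effects: str = ""


class GameSpec(BaseModel):
    """A game: its interaction type and ordered levels."""

    model_config = ConfigDict(frozen=True)

    type: GameType
    levels: tuple[LevelSpec, ...] = Field(min_length=1)


class SessionConfig(BaseModel):
    """Parameters of one game session: T trials of θ seconds each."""

    model_config = ConfigDict(frozen=True)

    level_index: int = Field(default=1, ge=1)
    n_trials: int = Field(default=10, ge=1, description="T, total tries")
    trial_limit: float = Field(default=60.0, gt=0.0, description="θ, seconds")
    seed: Optional[int] = None


class TrialRecord(BaseModel):
    """One trial's outcome and, where applicable, its response time."""

    model_config = ConfigDict(frozen=True)

    index: int = Field(ge=0, description="0-based position in the session")
    outcome: Outcome
    response_time: Optional[float] = Field(
        default=None, description="seconds from trial start to selection"
    )

    @model_validator(mode="after")
    def _response_time_consistency(self) -> "TrialRecord":
        responded = self.outcome in (Outcome.CORRECT, Outcome.COMMISSION)
        if responded and self.response_time is None:
            raise ValueError(f"{self.outcome.value} trial requires a response_time")
        if not responded and self.response_time is not None:
            raise ValueError(f"{self.outcome.value} trial must not carry a response_time")
        if self.response_time is not None and self.response_time <= 0:
            raise ValueError("response_time must be positive")
        return self


class SessionLog(BaseModel):
    """An ordered record of the trials of one session.

    The record-level invariants (positive response times, response time
    present iff the patient responded) are enforced at construction;
    the cross-record rules (contiguous indices, quit-is-last, response time
    within the trial limit) are checked by :func:`validate_session_log`,
    which reports violations instead of raising so that readers of external
    files can surface every problem at once.
    """

    model_config = ConfigDict(frozen=True)

    session_id: str = Field(min_length=1)
    config: SessionConfig = SessionConfig()
    trials: tuple[TrialRecord, ...] = ()

    @property
    def n_attempted(self) -> int:
        """Trials actually played (correct + commission + omission)."""
        return sum(1 for t in self.trials if t.outcome is not Outcome.QUIT)


class TreatmentProgram(BaseModel):
    """A set of sessions making up one treatment program."""

    model_config = ConfigDict(frozen=True)

    sessions: tuple[SessionLog, ...] = ()
    duration: float = Field(gt=0.0, description="maximum total minutes")


def validate_session_log(log: SessionLog) -> list[str]:
    """Check every session-level invariant and return the violations.

    Returns an empty list iff the log is fully valid. Each violation names
    the offending trial index and the rule broken. Violations are returned
    rather than raised so callers can report them all at once.
    """
    violations: list[str] = []
    theta = log.config.trial_limit

    for pos, trial in enumerate(log.trials):
        if trial.index != pos:
            violations.append(
                f"trial at position {pos}: index {trial.index} is not consecutive "
                f"(expected {pos})"
            )
        responded = trial.outcome in (Outcome.CORRECT, Outcome.COMMISSION)
        if responded:
            if trial.response_time is None:
                violations.append(
                    f"trial {trial.index}: {trial.outcome.value} outcome missing response_time"
                )
            elif not (0.0 < trial.response_time <= theta):
                violations.append(
                    f"trial {trial.index}: response_time {trial.response_time} "
                    f"outside (0, {theta}]"
                )
        elif trial.response_time is not None:
            violations.append(
                f"trial {trial.index}: {trial.outcome.value} outcome must not carry "
                "a response_time"
            )

    quit_positions = [p for p, t in enumerate(log.trials) if t.outcome is Outcome.QUIT]
    if len(quit_positions) > 1:
        violations.append(
            f"trial {log.trials[quit_positions[1]].index}: more than one quit record"
        )
    if quit_positions and quit_positions[0] != len(log.trials) - 1:
        violations.append(
            f"trial {log.trials[quit_positions[0]].index}: quit must be last"
        )

    if log.n_attempted > log.config.n_trials:
        violations.append(
            f"log has {log.n_attempted} attempted trials, more than "
            f"n_trials={log.config.n_trials}"
        )
    return violations
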