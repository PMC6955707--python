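from __future__ import annotations

from typing import Optional, Sequence

import pytest

from cptsim import Outcome, SessionConfig, SessionLog, TrialRecord

RESPONDED = ("correct", "commission")


def make_log(
    outcomes: Sequence[str],
    rts: Optional[Sequence[float]] = None,
    n_trials: int = 10,
    theta: float = 60.0,
    session_id: str = "s0",
) -> SessionLog:
    """Build a session log from outcome names, assigning response times in order.

    ``rts`` supplies one value per responded (correct/commission) trial.
    """
    rt_iter = iter(rts if rts is not None else [5.0] * len(outcomes))
    trials = []
    for i, name in enumerate(outcomes):
        rt = next(rt_iter) if name in RESPONDED else None
        trials.append(TrialRecord(index=i, outcome=Outcome(name), response_time=rt))
    return SessionLog(
        session_id=session_id,
        config=SessionConfig(n_trials=n_trials, trial_limit=theta),
        trials=tuple(trials),
    )


@pytest.fixture
def all_correct_log() -> SessionLog:
    return make_log(["correct"] * 10, rts=[5.0] * 10)


@pytest.fixture
def quit_first_log() -> SessionLog:
    return make_log(["quit"])
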