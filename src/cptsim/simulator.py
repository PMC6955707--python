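"""Stochastic patient-behaviour simulator producing trial-level session logs.

Each attempted trial is an independent categorical draw: omission with
probability ``p_omit``, commission with ``p_commit``, correct otherwise.
Before every trial the patient may abandon the session with probability
``p_quit``; a quit consumes no trial slot, so all remaining slots count as
uncompleted tries (K). Response times for correct and commission trials are
drawn from a normal distribution truncated to (crt_floor, θ], centred on an
improvement schedule: the expected CRT decreases linearly per trial and per
session (down to a floor), emulating a patient growing familiar with the
game across a treatment program.

All stochastic operations take an explicit ``numpy.random.Generator``;
there is no hidden global state, and identical seeds reproduce identical
log streams bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .model import Outcome, SessionConfig, SessionLog, TrialRecord

__all__ = [
    "ImprovementSchedule",
    "BehaviorModel",
    "BehaviorEstimate",
    "simulate_trial",
    "simulate_session",
    "simulate_program",
    "estimate_behavior",
    "calibrate_mu",
]


class ImprovementSchedule(BaseModel):
    """Linear decay of the expected correct response time.

    expected CRT(session s, trial t) = max(floor, mu0 − delta_session·s −
    delta_trial·t), non-increasing in both indices.
    """

    model_config = ConfigDict(frozen=True)

    mu0: float = Field(gt=0.0, description="baseline mean CRT, seconds")
    delta_session: float = Field(default=0.0, ge=0.0, description="per-session decrement, s")
    delta_trial: float = Field(default=0.0, ge=0.0, description="per-trial decrement, s")
    floor: float = Field(default=1.0, gt=0.0, description="minimum mean CRT, s")

    def mean_crt(self, session_idx: int, trial_idx: int) -> float:
        return max(
            self.floor,
            self.mu0 - self.delta_session * session_idx - self.delta_trial * trial_idx,
        )


class BehaviorModel(BaseModel):
    """Per-trial outcome probabilities plus the response-time model."""

    model_config = ConfigDict(frozen=True)

    p_omit: float = Field(ge=0.0, le=1.0)
    p_commit: float = Field(ge=0.0, le=1.0)
    p_quit: float = Field(default=0.0, ge=0.0, le=1.0)
    crt_schedule: ImprovementSchedule
    crt_noise_sd: float = Field(default=14.0, ge=0.0, description="seconds")
    crt_floor: float = Field(default=0.5, gt=0.0, description="lower truncation, s")

    @model_validator(mode="after")
    def _probability_budget(self) -> "BehaviorModel":
        if self.p_omit + self.p_commit > 1.0 + 1e-12:
            raise ValueError(
                f"p_omit + p_commit = {self.p_omit + self.p_commit} exceeds 1"
            )
        return self


@dataclass(frozen=True)
class BehaviorEstimate:
    """Moment estimates of the behaviour probabilities with binomial SEs."""

    p_omit: float
    p_commit: float
    p_quit: float
    se_omit: float
    se_commit: float
    se_quit: float
    n_attempted: int
    n_quit_opportunities: int


def _draw_crt(
    behavior: BehaviorModel,
    session_idx: int,
    trial_idx: int,
    theta: float,
    rng: np.random.Generator,
) -> float:
    mu = behavior.crt_schedule.mean_crt(session_idx, trial_idx)
    lo, hi = behavior.crt_floor, theta
    if behavior.crt_noise_sd == 0.0:
        return min(max(mu, math.nextafter(lo, hi)), hi)
    sd = behavior.crt_noise_sd
    # inverse-CDF draw of normal(mu, sd) truncated to (lo, hi]
    cdf_lo = ndtr((lo - mu) / sd)
    cdf_hi = ndtr((hi - mu) / sd)
    u = cdf_lo + rng.random() * (cdf_hi - cdf_lo)
    x = mu + sd * float(ndtri(u))
    return min(max(x, math.nextafter(lo, hi)), hi)


def simulate_trial(
    behavior: BehaviorModel,
    session_idx: int,
    trial_idx: int,
    theta: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Draw one trial: quit check first, then the outcome and response time."""
    if rng.random() < behavior.p_quit:
        return TrialRecord(index=trial_idx, outcome=Outcome.QUIT)
    u = rng.random()
    if u < behavior.p_omit:
        return TrialRecord(index=trial_idx, outcome=Outcome.OMISSION)
    if u < behavior.p_omit + behavior.p_commit:
        rt = _draw_crt(behavior, session_idx, trial_idx, theta, rng)
        return TrialRecord(index=trial_idx, outcome=Outcome.COMMISSION, response_time=rt)
    rt = _draw_crt(behavior, session_idx, trial_idx, theta, rng)
    return TrialRecord(index=trial_idx, outcome=Outcome.CORRECT, response_time=rt)


def simulate_session(
    config: SessionConfig,
    behavior: BehaviorModel,
    session_idx: int = 0,
    rng: Optional[np.random.Generator] = None,
    *,
    session_id: Optional[str] = None,
    max_attempts: Optional[int] = None,
) -> SessionLog:
    """Simulate one session of up to ``config.n_trials`` trials.

    The session stops at the first quit or after the last trial. With
    ``max_attempts`` set below ``n_trials``, the patient deterministically
    walks away after that many attempted trials without a quit record,
    leaving the remaining slots uncompleted (useful to pin K exactly).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    limit = config.n_trials if max_attempts is None else min(max_attempts, config.n_trials)
    trials: list[TrialRecord] = []
    for t in range(limit):
        record = simulate_trial(behavior, session_idx, t, config.trial_limit, rng)
        trials.append(record)
        if record.outcome is Outcome.QUIT:
            break
    return SessionLog(
        session_id=session_id or f"s{session_idx:04d}",
        config=config,
        trials=tuple(trials),
    )


def simulate_program(
    n_sessions: int,
    config: SessionConfig,
    behavior: BehaviorModel,
    rng: Optional[np.random.Generator] = None,
) -> list[SessionLog]:
    """Simulate a treatment program of ``n_sessions`` consecutive sessions.

    Session s uses the schedule mean μ(s, t), so the expected per-session
    mean CRT is non-increasing across the program.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be at least 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [
        simulate_session(config, behavior, session_idx=s, rng=rng)
        for s in range(n_sessions)
    ]


def estimate_behavior(logs: Sequence[SessionLog]) -> BehaviorEstimate:
    """Recover behaviour probabilities from observed logs by method of moments.

    p̂_omit and p̂_commit are pooled outcome frequencies over attempted
    trials; p̂_quit is the fraction of quit opportunities (one before each
    reached trial) that ended the session. Standard errors use the binomial
    formula sqrt(p̂(1−p̂)/n).
    """
    if not logs:
        raise ValueError("estimate_behavior requires at least one log")
    n_att = n_oe = n_ce = n_quits = n_opp = 0
    for log in logs:
        for t in log.trials:
            n_opp += 1  # one quit decision precedes every reached trial
            if t.outcome is Outcome.QUIT:
                n_quits += 1
            else:
                n_att += 1
                if t.outcome is Outcome.OMISSION:
                    n_oe += 1
                elif t.outcome is Outcome.COMMISSION:
                    n_ce += 1

    def _se(p: float, n: int) -> float:
        return math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")

    p_omit = n_oe / n_att if n_att else 0.0
    p_commit = n_ce / n_att if n_att else 0.0
    p_quit = n_quits / n_opp if n_opp else 0.0
    return BehaviorEstimate(
        p_omit=p_omit,
        p_commit=p_commit,
        p_quit=p_quit,
        se_omit=_se(p_omit, n_att),
        se_commit=_se(p_commit, n_att),
        se_quit=_se(p_quit, n_opp),
        n_attempted=n_att,
        n_quit_opportunities=n_opp,
    )


def calibrate_mu(
    target_mean: float, noise_sd: float, lo: float, hi: float
) -> float:
    """Location μ such that a normal(μ, sd) truncated to (lo, hi] has the
    given mean.

    Truncation pulls the mean toward the interval centre, so simulating with
    μ = target would bias the observed mean CRT; this inverts that bias.
    """
    if not (lo < target_mean <= hi):
        raise ValueError(f"target mean {target_mean} outside ({lo}, {hi}]")
    if noise_sd == 0.0:
        return target_mean

    def gap(mu: float) -> float:
        a, b = (lo - mu) / noise_sd, (hi - mu) / noise_sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=noise_sd) - target_mean

    span = 10.0 * noise_sd + (hi - lo)
    return float(optimize.brentq(gap, target_mean - span, target_mean + span, xtol=1e-10))
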