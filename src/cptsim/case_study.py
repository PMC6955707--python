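"""Two-part simulated case study over fixed phase parameter sets.

Part 1 (three phases, 20 sessions each) varies the split between correct
and incorrect tries with full engagement (K = 0), isolating the effect of
the error factor on the performance index. Part 2 (four phases) sets all
errors to zero and varies engagement through the number of uncompleted
tries K. Each phase is scored three ways:

* summary mode  — directly from the phase tallies and mean CRT;
* curve mode    — 20 per-session PI values under a linear within-phase
  improvement of the mean CRT (PI is affine in M, so the curve's mean
  equals the summary-mode PI);
* generative mode — Monte-Carlo sessions from a behaviour model calibrated
  to the phase, reporting deviations from summary mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .metrics import SessionMetrics, round_percent, score_session, score_summary
from .model import SessionConfig
from .simulator import BehaviorModel, ImprovementSchedule, calibrate_mu, simulate_session

__all__ = [
    "PhaseSpec",
    "PhaseResult",
    "DeviationReport",
    "PART1_PHASES",
    "PART2_PHASES",
    "run_part1",
    "run_part2",
    "pi_curve",
    "generative_check",
    "phase_table",
    "curve_table",
]

_METRIC_KEYS = ("GF", "IAF", "IMF", "EF", "CRF", "PI")


class PhaseSpec(BaseModel):
    """One phase: constant per-session tallies and the phase mean CRT."""

    model_config = ConfigDict(frozen=True)

    label: str
    n_sessions: int = Field(default=20, ge=1)
    C: int = Field(ge=0)
    OE: int = Field(ge=0)
    CE: int = Field(ge=0)
    K: int = Field(ge=0)
    mean_crt: Optional[float] = None
    theta: float = Field(default=60.0, gt=0.0)

    @model_validator(mode="after")
    def _consistent(self) -> "PhaseSpec":
        if self.C + self.OE + self.CE + self.K != 10:
            raise ValueError("phase tallies must sum to the 10 tries of a session")
        if self.C > 0 and self.mean_crt is None:
            raise ValueError("mean_crt required when C > 0")
        if self.mean_crt is not None and not (0.0 < self.mean_crt <= self.theta):
            raise ValueError(f"mean_crt={self.mean_crt} outside (0, θ={self.theta}]")
        return self


PART1_PHASES: tuple[PhaseSpec, ...] = (
    PhaseSpec(label="part1-phase1", C=3, OE=3, CE=4, K=0, mean_crt=25.13),
    PhaseSpec(label="part1-phase2", C=5, OE=3, CE=2, K=0, mean_crt=23.71),
    PhaseSpec(label="part1-phase3", C=8, OE=1, CE=1, K=0, mean_crt=21.81),
)

PART2_PHASES: tuple[PhaseSpec, ...] = (
    PhaseSpec(label="part2-phase1", C=3, OE=0, CE=0, K=7, mean_crt=25.13),
    PhaseSpec(label="part2-phase2", C=5, OE=0, CE=0, K=5, mean_crt=23.93),
    PhaseSpec(label="part2-phase3", C=7, OE=0, CE=0, K=3, mean_crt=22.94),
    PhaseSpec(label="part2-phase4", C=10, OE=0, CE=0, K=0, mean_crt=21.62),
)


@dataclass(frozen=True)
class PhaseResult:
    """Summary-mode metrics of one phase plus its rounded table row."""

    spec: PhaseSpec
    metrics: SessionMetrics
    percentages: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class DeviationReport:
    """Absolute gaps between Monte-Carlo mean metrics and summary mode."""

    phase: str
    replicates: int
    summary: dict[str, float]
    monte_carlo: dict[str, float]
    deviation: dict[str, float]


def _score_phase(spec: PhaseSpec) -> PhaseResult:
    metrics = score_summary(
        C=spec.C, OE=spec.OE, CE=spec.CE, K=spec.K, M=spec.mean_crt, theta=spec.theta
    )
    percentages = {k: round_percent(getattr(metrics, k)) for k in _METRIC_KEYS}
    return PhaseResult(spec=spec, metrics=metrics, percentages=percentages)


def run_part1() -> list[PhaseResult]:
    """Score the three error-variation phases (K = 0 throughout)."""
    return [_score_phase(p) for p in PART1_PHASES]


def run_part2() -> list[PhaseResult]:
    """Score the four engagement-variation phases (OE = CE = 0 throughout)."""
    return [_score_phase(p) for p in PART2_PHASES]


def pi_curve(
    phase: PhaseSpec,
    start_M: Optional[float] = None,
    end_M: Optional[float] = None,
) -> np.ndarray:
    """Per-session PI under a linear mean-CRT improvement across the phase.

    Session means run linearly from ``start_M`` down to ``end_M`` (defaults:
    phase mean ± 5 s) and must average to the phase mean, so that the
    curve's mean equals the summary-mode PI — PI is affine in M at fixed
    tallies. The curve is non-decreasing because PI falls with CRF.
    """
    if phase.mean_crt is None:
        raise ValueError("pi_curve requires a phase with correct tries")
    if start_M is None:
        start_M = phase.mean_crt + 5.0
    if end_M is None:
        end_M = phase.mean_crt - 5.0
    if start_M < end_M:
        raise ValueError("start_M must be ≥ end_M (response times improve)")
    for name, v in (("start_M", start_M), ("end_M", end_M)):
        if not (0.0 < v <= phase.theta):
            raise ValueError(f"{name}={v} outside (0, θ={phase.theta}]")
    if abs((start_M + end_M) / 2.0 - phase.mean_crt) > 1e-9:
        raise ValueError("session means must average to the phase mean CRT")
    session_means = np.linspace(start_M, end_M, phase.n_sessions)
    return np.array(
        [
            score_summary(
                C=phase.C, OE=phase.OE, CE=phase.CE, K=phase.K, M=float(m),
                theta=phase.theta,
            ).PI
            for m in session_means
        ]
    )


def behavior_for_phase(phase: PhaseSpec, crt_noise_sd: float = 14.0) -> BehaviorModel:
    """Behaviour model whose expected per-session tallies match the phase.

    Outcome probabilities are the phase's error fractions over attempted
    tries. Engagement is matched deterministically (the session stops after
    C+I attempts) rather than through a stochastic quit, because the phase
    tables show a constant K per session. The response-time location is
    calibrated so the truncated-normal mean equals the phase mean CRT.
    """
    attempted = phase.C + phase.OE + phase.CE
    crt_floor = 0.5
    if attempted == 0:
        mu0 = crt_floor * 2
    else:
        assert phase.mean_crt is not None
        mu0 = calibrate_mu(phase.mean_crt, crt_noise_sd, crt_floor, phase.theta)
    return BehaviorModel(
        p_omit=phase.OE / attempted if attempted else 0.0,
        p_commit=phase.CE / attempted if attempted else 0.0,
        p_quit=0.0,
        crt_schedule=ImprovementSchedule(mu0=mu0, floor=min(mu0, 1.0)),
        crt_noise_sd=crt_noise_sd,
        crt_floor=crt_floor,
    )


def generative_check(
    phase: PhaseSpec,
    replicates: int,
    rng: np.random.Generator,
) -> DeviationReport:
    """Simulate the phase and report |Monte-Carlo mean − summary| per metric.

    Bridges the trial-level simulator and summary-mode scoring: with a
    behaviour model calibrated to the phase, the Monte-Carlo means of every
    factor and of PI should sit within sampling error of the summary values.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    summary = _score_phase(phase).metrics
    behavior = behavior_for_phase(phase)
    config = SessionConfig(n_trials=10, trial_limit=phase.theta)
    attempted = phase.C + phase.OE + phase.CE

    sums = dict.fromkeys(_METRIC_KEYS, 0.0)
    for _ in range(replicates):
        log = simulate_session(config, behavior, rng=rng, max_attempts=attempted)
        scored = score_session(log)
        for k in _METRIC_KEYS:
            sums[k] += getattr(scored, k)
    mc = {k: sums[k] / replicates for k in _METRIC_KEYS}
    ref = {k: getattr(summary, k) for k in _METRIC_KEYS}
    return DeviationReport(
        phase=phase.label,
        replicates=replicates,
        summary=ref,
        monte_carlo=mc,
        deviation={k: abs(mc[k] - ref[k]) for k in _METRIC_KEYS},
    )


def phase_table(results: list[PhaseResult]) -> pd.DataFrame:
    """One row per phase with the tallies, M and integer-percent measures."""
    rows = []
    for r in results:
        rows.append(
            {
                "phase": r.spec.label,
                "C": r.spec.C,
                "OE": r.spec.OE,
                "CE": r.spec.CE,
                "K": r.spec.K,
                "IAF": r.percentages["IAF"],
                "IMF": r.percentages["IMF"],
                "EF": r.percentages["EF"],
                "GF": r.percentages["GF"],
                "M": r.spec.mean_crt,
                "avg_PI": r.percentages["PI"],
            }
        )
    return pd.DataFrame(rows)


def curve_table(phases: tuple[PhaseSpec, ...]) -> pd.DataFrame:
    """Long-format per-session PI curves, one row per (phase, session)."""
    rows = []
    for phase in phases:
        for s, pi in enumerate(pi_curve(phase)):
            rows.append({"phase": phase.label, "session": s, "PI": float(pi)})
    return pd.DataFrame(rows)
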