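"""Session performance measures for game-based continuous performance tests.

Given a session of T tries with per-trial limit θ, the tallies are

    C   correct tries
    OE  omission errors (no response; inattention)
    CE  commission errors (non-target response; impulsivity)
    I   incorrect tries,    I = OE + CE
    K   uncompleted tries,  T = C + I + K

and the measures are

    M    mean correct response time (CRT), seconds
    SD   sample standard deviation of the CRTs, seconds
    GF   engagement factor        (C + I) / T
    IAF  inattention factor       OE / (C + I)
    IMF  impulsivity factor       CE / (C + I)
    EF   error factor             (OE + CE) / (C + I)  =  IAF + IMF
    CRF  correct response factor  ΣCRT / (C·θ)
    PI   performance index        [((1 − CRF) + (1 − EF)) / 2] · GF
    GT   actual elapsed game time, seconds
    ST   maximum session time, T·θ seconds

All factors are fractions in [0, 1]. Empty denominators fall back to 0
(and M to absent) so that an immediately-abandoned session scores PI = 0,
the worst outcome.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import Outcome, SessionLog, validate_session_log

__all__ = [
    "SessionCounts",
    "SessionMetrics",
    "tally",
    "mean_sd_crt",
    "engagement_factor",
    "inattention_factor",
    "impulsivity_factor",
    "error_factor",
    "correct_response_factor",
    "performance_index",
    "score_session",
    "score_summary",
    "round_percent",
]


class SessionCounts(BaseModel):
    """Outcome tallies for one session; I and T are derived on construction."""

    model_config = ConfigDict(frozen=True)

    C: int = Field(ge=0)
    OE: int = Field(ge=0)
    CE: int = Field(ge=0)
    K: int = Field(ge=0)

    @property
    def I(self) -> int:  # noqa: E743 - domain symbol
        return self.OE + self.CE

    @property
    def T(self) -> int:
        return self.C + self.I + self.K

    @property
    def attempted(self) -> int:
        return self.C + self.I


class SessionMetrics(BaseModel):
    """All performance measures of one session.

    ``M``, ``SD`` and ``GT`` are ``None`` when not derivable: M when no
    correct try exists, SD and GT when scoring from a printed summary
    rather than a trial stream.
    """

    model_config = ConfigDict(frozen=True)

    counts: SessionCounts
    M: Optional[float] = None
    SD: Optional[float] = None
    GF: float = Field(ge=0.0, le=1.0)
    IAF: float = Field(ge=0.0, le=1.0)
    IMF: float = Field(ge=0.0, le=1.0)
    EF: float = Field(ge=0.0, le=1.0)
    CRF: float = Field(ge=0.0, le=1.0)
    PI: float = Field(ge=0.0, le=1.0)
    GT: Optional[float] = None
    ST: float = Field(gt=0.0)
    theta: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _ranges(self) -> "SessionMetrics":
        if self.GT is not None and not (0.0 <= self.GT <= self.ST + 1e-9):
            raise ValueError(f"GT={self.GT} outside [0, ST={self.ST}]")
        return self


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, half away from zero.

    Matches the table formatting convention (0.715 → 72%).
    """
    return int(math.floor(fraction * 100.0 + 0.5))


def tally(log: SessionLog) -> SessionCounts:
    """Count outcomes of a validated log; K is the remainder T − C − I.

    T is the configured number of tries, so trial slots never reached
    (after a quit, or simply unplayed) all count toward K.
    """
    violations = validate_session_log(log)
    if violations:
        raise ValueError(f"invalid session log: {violations[0]}")
    c = sum(1 for t in log.trials if t.outcome is Outcome.CORRECT)
    oe = sum(1 for t in log.trials if t.outcome is Outcome.OMISSION)
    ce = sum(1 for t in log.trials if t.outcome is Outcome.COMMISSION)
    k = log.config.n_trials - c - oe - ce
    return SessionCounts(C=c, OE=oe, CE=ce, K=k)


def mean_sd_crt(crts: Sequence[float] | Iterable[float]) -> tuple[Optional[float], float]:
    """Mean and sample standard deviation (divisor C−1) of correct response times.

    With a single observation SD is 0 by convention; with none, M is None.
    Non-positive response times are rejected.
    """
    values = list(crts)
    if any(v <= 0 for v in values):
        raise ValueError("response times must be positive")
    c = len(values)
    if c == 0:
        return None, 0.0
    mean = sum(values) / c
    if c == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (c - 1)
    return mean, math.sqrt(var)


def engagement_factor(counts: SessionCounts) -> float:
    """GF = (C + I)/T — the fraction of tries the patient attempted."""
    if counts.T == 0:
        raise ValueError("engagement factor undefined for T = 0")
    return counts.attempted / counts.T


def inattention_factor(counts: SessionCounts) -> float:
    """IAF = OE/(C + I); 0 when nothing was attempted."""
    if counts.attempted == 0:
        return 0.0
    return counts.OE / counts.attempted


def impulsivity_factor(counts: SessionCounts) -> float:
    """IMF = CE/(C + I); 0 when nothing was attempted."""
    if counts.attempted == 0:
        return 0.0
    return counts.CE / counts.attempted


def error_factor(counts: SessionCounts) -> float:
    """EF = (OE + CE)/(C + I) = IAF + IMF; 0 when nothing was attempted.

    Computed as IAF + IMF so the additivity identity holds bit-exactly.
    """
    return inattention_factor(counts) + impulsivity_factor(counts)


def correct_response_factor(sum_crt: float, C: int, theta: float) -> float:
    """CRF = ΣCRT/(C·θ) — correct response time relative to its maximum.

    Only correct tries enter; commission response times are excluded.
    With no correct try CRF is 0 by convention.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if C == 0:
        if sum_crt:
            raise ValueError("sum_crt must be 0 when C = 0")
        return 0.0
    if sum_crt > C * theta * (1 + 1e-12):
        raise ValueError(f"sum_crt={sum_crt} exceeds C·θ={C * theta}: impossible log")
    return min(sum_crt / (C * theta), 1.0)


def performance_index(
    CRF: float, EF: float, GF: float, *, gt_st_ratio: Optional[float] = None
) -> float:
    """PI = [((1−CRF) + (1−EF))/2] · GF, the composite session score.

    Fast, accurate, engaged play scores high: PI decreases in CRF (slower
    correct responses) and EF (more errors), and scales with engagement GF.

    ``gt_st_ratio`` enables an off-by-default variant that also penalises
    total elapsed game time GT relative to the session maximum ST, averaging
    (1−GT/ST) in as a third term. The standard two-term form is the one the
    reference tables validate.
    """
    for name, v in (("CRF", CRF), ("EF", EF), ("GF", GF)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    if gt_st_ratio is None:
        return ((1.0 - CRF) + (1.0 - EF)) / 2.0 * GF
    if not (0.0 <= gt_st_ratio <= 1.0):
        raise ValueError(f"gt_st_ratio={gt_st_ratio} outside [0, 1]")
    return ((1.0 - CRF) + (1.0 - EF) + (1.0 - gt_st_ratio)) / 3.0 * GF


def score_session(log: SessionLog) -> SessionMetrics:
    """Compute every session measure from a trial-level log.

    GT sums all recorded response times plus a full θ per omission
    (an omission means the trial timer expired); a quit adds nothing.
    """
    counts = tally(log)
    theta = log.config.trial_limit
    crts = [
        t.response_time
        for t in log.trials
        if t.outcome is Outcome.CORRECT and t.response_time is not None
    ]
    m, sd = mean_sd_crt(crts)
    gt = (
        sum(t.response_time for t in log.trials if t.response_time is not None)
        + counts.OE * theta
    )
    return SessionMetrics(
        counts=counts,
        M=m,
        SD=sd,
        GF=engagement_factor(counts),
        IAF=inattention_factor(counts),
        IMF=impulsivity_factor(counts),
        EF=error_factor(counts),
        CRF=correct_response_factor(sum(crts), counts.C, theta),
        PI=performance_index(
            correct_response_factor(sum(crts), counts.C, theta),
            error_factor(counts),
            engagement_factor(counts),
        ),
        GT=gt,
        ST=counts.T * theta,
        theta=theta,
    )


def score_summary(
    C: int,
    OE: int,
    CE: int,
    K: int,
    M: Optional[float],
    theta: float = 60.0,
) -> SessionMetrics:
    """Score a session from its printed summary (tallies + mean CRT).

    Uses ΣCRT = C·M, so the factor and PI values agree exactly with
    :func:`score_session` on any log with the same tallies and mean CRT.
    SD and GT are not derivable from a summary and are reported absent.
    """
    counts = SessionCounts(C=C, OE=OE, CE=CE, K=K)
    if counts.T == 0:
        raise ValueError("inconsistent counts: T = 0")
    if C > 0:
        if M is None:
            raise ValueError("M is required when C > 0")
        if not (0.0 < M <= theta):
            raise ValueError(f"M={M} outside (0, θ={theta}]")
        sum_crt = C * M
    else:
        if M is not None:
            raise ValueError("M must be absent when C = 0")
        sum_crt = 0.0
    crf = correct_response_factor(sum_crt, C, theta)
    ef = error_factor(counts)
    gf = engagement_factor(counts)
    return SessionMetrics(
        counts=counts,
        M=M,
        SD=None,
        GF=gf,
        IAF=inattention_factor(counts),
        IMF=impulsivity_factor(counts),
        EF=ef,
        CRF=crf,
        PI=performance_index(crf, ef, gf),
        GT=None,
        ST=counts.T * theta,
        theta=theta,
    )
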