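"""Serialisation of session logs and metrics, and behaviour configuration.

Trial streams are stored flat, one row (CSV) or object (JSONL) per trial,
with the columns

    session_id, trial_index, outcome, response_time_s, trial_limit_s, n_trials

Trial indices are 0-based. ``response_time_s`` is empty (CSV) or null
(JSONL) exactly for omission and quit rows, and is written with at most
three decimal places. Both formats encode the same information and
round-trip exactly at that precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import yaml
from pydantic import ValidationError

from .model import Outcome, SessionConfig, SessionLog, TrialRecord, validate_session_log
from .simulator import BehaviorModel, ImprovementSchedule

__all__ = [
    "FIELDNAMES",
    "LogParseError",
    "write_logs",
    "read_logs",
    "write_metrics",
    "load_behavior_config",
]

FIELDNAMES = (
    "session_id",
    "trial_index",
    "outcome",
    "response_time_s",
    "trial_limit_s",
    "n_trials",
)

Destination = Union[str, Path, IO[str]]


class LogParseError(ValueError):
    """A malformed row in an external trial stream; carries the row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _format_rt(rt: float | None) -> str:
    if rt is None:
        return ""
    return format(round(rt, 3), ".10g")


def _rows(logs: Iterable[SessionLog]) -> Iterable[dict]:
    for log in logs:
        for trial in log.trials:
            yield {
                "session_id": log.session_id,
                "trial_index": trial.index,
                "outcome": trial.outcome.value,
                "response_time_s": _format_rt(trial.response_time),
                "trial_limit_s": format(log.config.trial_limit, ".10g"),
                "n_trials": log.config.n_trials,
            }


def _open(destination: Destination, mode: str):
    if isinstance(destination, (str, Path)):
        return open(destination, mode, encoding="utf-8", newline=""), True
    return destination, False


def write_logs(logs: Sequence[SessionLog], destination: Destination, format: str = "jsonl") -> None:
    """Write session logs as flat trial rows in ``jsonl`` or ``csv`` format."""
    handle, owned = _open(destination, "w")
    try:
        if format == "csv":
            writer = csv.DictWriter(handle, fieldnames=FIELDNAMES)
            writer.writeheader()
            for row in _rows(logs):
                writer.writerow(row)
        elif format == "jsonl":
            for row in _rows(logs):
                obj = dict(row)
                obj["response_time_s"] = (
                    None if obj["response_time_s"] == "" else float(obj["response_time_s"])
                )
                obj["trial_index"] = int(obj["trial_index"])
                obj["trial_limit_s"] = float(obj["trial_limit_s"])
                obj["n_trials"] = int(obj["n_trials"])
                handle.write(json.dumps(obj) + "\n")
        else:
            raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'csv')")
    finally:
        if owned:
            handle.close()


def _parse_row(row: dict, rownum: int) -> dict:
    try:
        outcome = Outcome(str(row["outcome"]))
    except (ValueError, KeyError):
        raise LogParseError(rownum, f"unknown outcome token {row.get('outcome')!r}")
    rt_raw = row.get("response_time_s")
    rt = None if rt_raw in (None, "") else float(rt_raw)
    try:
        trial = TrialRecord(index=int(row["trial_index"]), outcome=outcome, response_time=rt)
    except (ValidationError, ValueError, KeyError) as exc:
        raise LogParseError(rownum, str(exc)) from None
    return {
        "session_id": str(row["session_id"]),
        "trial": trial,
        "trial_limit": float(row["trial_limit_s"]),
        "n_trials": int(row["n_trials"]),
    }


def read_logs(source: Destination, format: str = "jsonl") -> list[SessionLog]:
    """Read and validate session logs from a flat trial stream.

    Rows are grouped by ``session_id`` preserving order of first appearance;
    rows of distinct sessions may be interleaved. Any malformed row or
    reconstructed log that fails validation raises :class:`LogParseError`
    naming the offending row number (1-based, counting the CSV header).
    """
    handle, owned = _open(source, "r")
    try:
        parsed: list[tuple[int, dict]] = []
        if format == "csv":
            reader = csv.DictReader(handle)
            for rownum, row in enumerate(reader, start=2):
                parsed.append((rownum, _parse_row(row, rownum)))
        elif format == "jsonl":
            for rownum, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogParseError(rownum, f"invalid JSON: {exc}") from None
                parsed.append((rownum, _parse_row(row, rownum)))
        else:
            raise ValueError(f"unknown format {format!r} (expected 'jsonl' or 'csv')")
    finally:
        if owned:
            handle.close()

    sessions: dict[str, list[tuple[int, dict]]] = {}
    for rownum, rec in parsed:
        sessions.setdefault(rec["session_id"], []).append((rownum, rec))

    logs = []
    for session_id, recs in sessions.items():
        first_rownum, first = recs[0]
        config = SessionConfig(n_trials=first["n_trials"], trial_limit=first["trial_limit"])
        for rownum, rec in recs:
            if rec["n_trials"] != config.n_trials or rec["trial_limit"] != config.trial_limit:
                raise LogParseError(
                    rownum, f"session {session_id!r} has inconsistent configuration"
                )
        log = SessionLog(
            session_id=session_id,
            config=config,
            trials=tuple(rec["trial"] for _, rec in recs),
        )
        violations = validate_session_log(log)
        if violations:
            raise LogParseError(
                first_rownum, f"session {session_id!r} invalid: {violations[0]}"
            )
        logs.append(log)
    return logs


def write_metrics(scored: Sequence[tuple[str, "object"]], destination: Destination) -> None:
    """Write one CSV row of measures per session.

    ``scored`` pairs each session id with its :class:`~cptsim.metrics.SessionMetrics`.
    Absent values (M of a no-correct session, SD/GT in summary mode) are
    written empty.
    """
    fields = [
        "session_id", "C", "OE", "CE", "K", "T", "M", "SD",
        "GF", "IAF", "IMF", "EF", "CRF", "PI", "GT", "ST",
    ]
    handle, owned = _open(destination, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(fields)
        for session_id, m in scored:
            writer.writerow(
                [
                    session_id,
                    m.counts.C, m.counts.OE, m.counts.CE, m.counts.K, m.counts.T,
                    "" if m.M is None else format(m.M, ".6g"),
                    "" if m.SD is None else format(m.SD, ".6g"),
                    format(m.GF, ".6g"), format(m.IAF, ".6g"), format(m.IMF, ".6g"),
                    format(m.EF, ".6g"), format(m.CRF, ".6g"), format(m.PI, ".6g"),
                    "" if m.GT is None else format(m.GT, ".6g"),
                    format(m.ST, ".6g"),
                ]
            )
    finally:
        if owned:
            handle.close()


def load_behavior_config(source: Destination) -> BehaviorModel:
    """Load a behaviour model from YAML.

    Schema (all keys required)::

        p_omit: 0.3
        p_commit: 0.4
        p_quit: 0.0
        crt:
          mu0: 26.0
          delta_session: 0.15
          delta_trial: 0.05
          floor: 5.0
          noise_sd: 14.0
    """
    handle, owned = _open(source, "r")
    try:
        raw = yaml.safe_load(handle)
    finally:
        if owned:
            handle.close()
    if not isinstance(raw, dict):
        raise ValueError("behaviour config must be a YAML mapping")
    missing = {"p_omit", "p_commit", "p_quit", "crt"} - raw.keys()
    if missing:
        raise ValueError(f"behaviour config missing keys: {sorted(missing)}")
    crt = raw["crt"]
    if not isinstance(crt, dict):
        raise ValueError("behaviour config key 'crt' must be a mapping")
    crt_missing = {"mu0", "delta_session", "delta_trial", "floor", "noise_sd"} - crt.keys()
    if crt_missing:
        raise ValueError(f"behaviour config 'crt' missing keys: {sorted(crt_missing)}")
    try:
        schedule = ImprovementSchedule(
            mu0=crt["mu0"],
            delta_session=crt["delta_session"],
            delta_trial=crt["delta_trial"],
            floor=crt["floor"],
        )
        return BehaviorModel(
            p_omit=raw["p_omit"],
            p_commit=raw["p_commit"],
            p_quit=raw["p_quit"],
            crt_schedule=schedule,
            crt_noise_sd=crt["noise_sd"],
        )
    except ValidationError as exc:
        raise ValueError(f"invalid behaviour config: {exc}") from None
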