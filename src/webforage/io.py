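"""CSV formats and configuration files.

Session logs are one row per offer encounter; absent values (the
hidden delay on skips, missing ratings) are empty fields, never 0.
Configs are flat key-value text with section prefixes, e.g.
``task.delay_min = 3``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import AgentParams
from .task import NONE, Offer, TrialRecord

SESSION_COLUMNS = [
    "subject_id", "trial_index", "gallery", "low", "mid", "high", "is_risky",
    "choice", "realized_delay", "outcome_class", "rating", "decision_rt",
    "clock_start", "clock_end",
]


def session_log_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "trial_index": r.trial_index,
            "gallery": r.offer.gallery,
            "low": r.offer.low, "mid": r.offer.mid, "high": r.offer.high,
            "is_risky": int(r.offer.is_risky),
            "choice": r.choice,
            "realized_delay": r.realized_delay,
            "outcome_class": r.outcome_class if r.outcome_class != NONE else "none",
            "rating": r.rating,
            "decision_rt": r.decision_rt,
            "clock_start": r.clock_start,
            "clock_end": r.clock_end,
        })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_log(records: Sequence[TrialRecord], path) -> None:
    # times are already rounded to 6 decimals at simulation time, so the
    # default float repr round-trips exactly
    session_log_frame(records).to_csv(path, index=False)


def _record_from_row(row, line_no: int, strict: bool, problems: list) -> Optional[TrialRecord]:
    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    try:
        offer = Offer(str(row.gallery), int(row.low), int(row.mid), int(row.high))
        if bool(int(row.is_risky)) != offer.is_risky:
            raise ValueError("is_risky flag inconsistent with delays")
        return TrialRecord(
            subject_id=str(row.subject_id),
            trial_index=int(row.trial_index),
            offer=offer,
            choice=str(row.choice),
            realized_delay=_opt_int(row.realized_delay),
            outcome_class=None if pd.isna(row.outcome_class) else str(row.outcome_class),
            rating=_opt_int(row.rating),
            decision_rt=float(row.decision_rt),
            clock_start=float(row.clock_start),
            clock_end=float(row.clock_end),
        )
    except (ValueError, TypeError) as exc:
        problems.append(f"row {line_no}: {exc}")
        if strict:
            raise ValueError(f"invalid session log row {line_no}: {exc}") from exc
        return None


def read_session_log(path, strict: bool = True) -> tuple[list[TrialRecord], list[str]]:
    """Read and validate a session log.

    Returns (records, problems). In strict mode the first invariant
    violation raises; in lenient mode offending rows are dropped and
    reported with their line numbers.
    """
    df = pd.read_csv(path)
    if list(df.columns) != SESSION_COLUMNS:
        raise ValueError(
            f"malformed header: expected {SESSION_COLUMNS}, got {list(df.columns)}")
    problems: list[str] = []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = _record_from_row(row, i, strict, problems)
        if rec is not None:
            records.append(rec)
    return records, problems


# --------------------------------------------------------------------------
# Ground truth

def truth_frame(agents: Sequence[AgentParams]) -> pd.DataFrame:
    """Flatten agent ground truth to a CSV-ready table keyed by subject."""
    rows = []
    for a in agents:
        row = {
            "subject_id": a.subject_id,
            "beta": a.beta, "gamma0": a.gamma0, "gamma_E": a.gamma_E,
            "gamma": a.gamma, "E": a.E, "eta": a.eta,
            "rating_a": a.rating_a, "rating_b": a.rating_b, "rating_c": a.rating_c,
            "sigma_r": a.sigma_r, "alpha0": a.alpha0, "delta": a.delta,
            "sigma_rt": a.sigma_rt, "logk_delay": a.logk_delay,
            "logk_prob": a.logk_prob, "choice_sharpness": a.choice_sharpness,
            "age": a.age, "sex": a.sex, "ethnicity": a.ethnicity,
        }
        for g, t in zip(a.galleries, a.tau):
            row[f"tau_{g}"] = t
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Flat key-value config

def write_config(sections: dict, path) -> None:
    lines = []
    for section, kv in sections.items():
        for key, value in kv.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                value = ",".join(str(v) for v in value)
            lines.append(f"{section}.{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(text: str):
    text = text.strip()
    if "," in text:
        return tuple(_coerce(t) for t in text.split(","))
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path) -> dict:
    """Parse ``section.key = value`` lines into nested dicts."""
    sections: dict = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line or "." not in line.split("=", 1)[0]:
            raise ValueError(f"line {line_no}: expected 'section.key = value'")
        key_part, value = line.split("=", 1)
        section, key = key_part.strip().split(".", 1)
        sections.setdefault(section, {})[key.strip()] = _coerce(value)
    return sections


def dataclass_from_section(cls, section: dict):
    """Build a config dataclass from a parsed section, keeping defaults
    for unlisted fields."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


__all__ = [
    "SESSION_COLUMNS", "session_log_frame", "write_session_log",
    "read_session_log", "truth_frame", "write_config", "read_config",
    "dataclass_from_section",
]
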