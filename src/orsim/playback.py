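"""Headless session playback and timestamped response logs.

A session replays a fixed scenario script against a response stream (a human
transcript or a synthetic responder) and records every entry with its
scenario timestamp.  Subjects are identified only by an opaque pseudonymous
code, so raters downstream remain blinded to identity, gender, and
experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

import pandas as pd

from .errors import ValidationError
from .library import EventRecord
from .scenario import ScenarioScript

__all__ = ["CATEGORIES", "ResponseEntry", "SessionLog", "run_session", "write_log", "read_log"]

#: Closed vocabulary of response-entry categories.  Human raters in a live
#: study infer these from free text; here they are carried explicitly.
CATEGORIES = ("detection", "differential", "intervention", "distractor_answer", "other")

_LOG_COLUMNS = ["t", "subject_id", "category", "text", "scenario"]


@dataclass(frozen=True)
class ResponseEntry:
    t: int
    subject_id: str
    text: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        if self.t < 1:
            raise ValidationError(f"timestamp must be >= 1, got {self.t}")


@dataclass
class SessionLog:
    """Ordered, timestamped entries from one simulated lunch break."""

    scenario: str
    subject_id: str
    entries: List[ResponseEntry] = field(default_factory=list)
    manifest: Optional[List[EventRecord]] = None

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.subject_id != self.subject_id:
                raise ValidationError(
                    f"entry subject {e.subject_id!r} != log subject {self.subject_id!r}"
                )
        # stable sort: ties keep their original relative order
        self.entries = sorted(self.entries, key=lambda e: e.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"t": e.t, "subject_id": e.subject_id, "category": e.category,
                 "text": e.text, "scenario": self.scenario}
                for e in self.entries
            ],
            columns=_LOG_COLUMNS,
        )


def run_session(
    script: ScenarioScript,
    responder: Iterable[ResponseEntry],
    scenario: str = "",
    subject_id: Optional[str] = None,
) -> SessionLog:
    """Replay ``script`` against a response stream and log every entry.

    The script is not mutated; the log contains exactly the responder's
    entries in time order.  Entries beyond the scenario duration are
    rejected.
    """
    entries = list(responder)
    for e in entries:
        if not 1 <= e.t <= script.duration:
            raise ValidationError(
                f"entry at t={e.t} outside scenario duration {script.duration}"
            )
    if subject_id is None:
        subjects = {e.subject_id for e in entries}
        if len(subjects) > 1:
            raise ValidationError(f"entries from multiple subjects: {sorted(subjects)}")
        subject_id = subjects.pop() if subjects else "anonymous"
    return SessionLog(scenario=scenario, subject_id=subject_id, entries=entries)


def write_log(log: SessionLog, path: str | Path) -> Path:
    """Write a session log as CSV (columns t, subject_id, category, text,
    scenario)."""
    path = Path(path)
    log.to_frame().to_csv(path, index=False)
    return path


def read_log(path: str | Path) -> SessionLog:
    """Read a session-log CSV back into a :class:`SessionLog`."""
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"log file missing columns: {missing}")
    scenarios = set(frame["scenario"].astype(str)) or {""}
    subjects = set(frame["subject_id"].astype(str)) or {""}
    if len(scenarios) > 1:
        raise ValidationError(f"log file mixes scenarios: {sorted(scenarios)}")
    if len(subjects) > 1:
        raise ValidationError(f"log file mixes subjects: {sorted(subjects)}")
    entries = [
        ResponseEntry(
            t=int(row.t),
            subject_id=str(row.subject_id),
            text=str(row.text),
            category=str(row.category),
        )
        for row in frame.itertuples()
    ]
    return SessionLog(
        scenario=scenarios.pop() if len(frame) else "",
        subject_id=subjects.pop() if len(frame) else "anonymous",
        entries=entries,
    )
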