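"""Per-second scenario scripts and threshold-based alarm annunciation.

A scenario script is the machine-readable form of one simulated intraoperative
"lunch break": a table with one row per second, a timestamp column, one column
per physiological or ventilator parameter, and one binary column per alarm
identifier.  Alarm columns are a pure function of the parameter tracks and a
rule set: a cell is 1 exactly while the rule's threshold condition holds
(non-latching, level-triggered), so re-evaluating is idempotent.

Alarm identifiers are symbolic names for the IEC 60601-1-8 alarm categories
and priorities (e.g. ``cardmed`` = medium-priority cardiac alarm).  Audio
synthesis of the IEC melodies and on-screen rendering are out of scope; the
identifiers are carried as opaque strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, LengthMismatchError, SchemaError, ValidationError

__all__ = [
    "PARAMETER_VOCABULARY",
    "PARAMETER_BOUNDS",
    "AlarmRule",
    "ScenarioScript",
    "assemble_script",
    "evaluate_alarms",
    "first_alarm_time",
    "write_script",
    "read_script",
    "load_rules",
    "default_rules",
]

#: Recognised parameter identifiers with units.
PARAMETER_VOCABULARY: tuple[str, ...] = (
    "HR",        # heart rate [bpm]
    "SpO2",      # peripheral oxygen saturation [%]
    "NIBP_sys",  # non-invasive systolic blood pressure [mmHg]
    "NIBP_dia",  # non-invasive diastolic blood pressure [mmHg]
    "MAP",       # mean arterial pressure [mmHg]
    "EtCO2",     # end-tidal CO2 [mmHg]
    "RR",        # respiratory rate [breaths/min]
    "PIP",       # peak inspiratory pressure [cmH2O]
    "TV",        # tidal volume [mL]
    "agent",     # volatile agent concentration [%]
)

#: Physiologically plausible (min, max) per parameter, enforced on write.
PARAMETER_BOUNDS: Dict[str, tuple[float, float]] = {
    "HR": (0.0, 300.0),
    "SpO2": (0.0, 100.0),
    "NIBP_sys": (0.0, 300.0),
    "NIBP_dia": (0.0, 200.0),
    "MAP": (0.0, 250.0),
    "EtCO2": (0.0, 120.0),
    "RR": (0.0, 60.0),
    "PIP": (0.0, 80.0),
    "TV": (0.0, 2000.0),
    "agent": (0.0, 10.0),
}

_PRIORITIES = ("low", "medium", "high")
_DIRECTIONS = ("low", "high")


@dataclass(frozen=True)
class AlarmRule:
    """One threshold rule: annunciate ``alarm_id`` while the condition holds.

    ``direction="low"`` fires when the parameter value is strictly below the
    threshold; ``"high"`` when strictly above.  Strict inequality matches the
    convention that an alarm sounds the first second a value *drops below*
    its limit.
    """

    parameter: str
    direction: str
    threshold: float
    priority: str
    alarm_id: str

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise DomainError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        if self.priority not in _PRIORITIES:
            raise DomainError(f"priority must be one of {_PRIORITIES}, got {self.priority!r}")
        if not math.isfinite(self.threshold):
            raise DomainError("threshold must be finite")

    def condition(self, values: np.ndarray) -> np.ndarray:
        if self.direction == "low":
            return values < self.threshold
        return values > self.threshold


def validate_rule_set(rules: Sequence[AlarmRule]) -> None:
    """Check uniqueness of (parameter, direction) and threshold ordering."""
    seen: Dict[tuple[str, str], float] = {}
    for r in rules:
        key = (r.parameter, r.direction)
        if key in seen:
            raise ValidationError(f"duplicate rule for {key}")
        seen[key] = r.threshold
    for param in {p for p, _ in seen}:
        lo = seen.get((param, "low"))
        hi = seen.get((param, "high"))
        if lo is not None and hi is not None and not lo < hi:
            raise ValidationError(
                f"{param}: low threshold {lo} must be < high threshold {hi}"
            )


@dataclass
class ScenarioScript:
    """A per-second scenario table.

    Timestamps are implicit: integer seconds ``1..duration`` (the header row
    of the file layout is not counted).  All tracks and alarm columns share
    the same length.
    """

    tracks: Dict[str, np.ndarray]
    alarms: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tracks:
            raise DomainError("script needs at least one parameter track")
        self.tracks = {k: np.asarray(v, dtype=float) for k, v in self.tracks.items()}
        lengths = {k: len(v) for k, v in self.tracks.items()}
        if len(set(lengths.values())) != 1:
            raise LengthMismatchError(f"track lengths differ: {lengths}")
        n = next(iter(lengths.values()))
        if n < 1:
            raise DomainError("scenario duration must be at least 1 second")
        for k, v in self.tracks.items():
            if v.ndim != 1:
                raise ValidationError(f"track {k!r} must be one-dimensional")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"track {k!r} contains non-finite values")
        coerced = {}
        for k, v in self.alarms.items():
            arr = np.asarray(v)
            if len(arr) != n:
                raise LengthMismatchError(
                    f"alarm column {k!r} has length {len(arr)}, expected {n}"
                )
            if not np.isin(arr, (0, 1)).all():
                bad = int(np.flatnonzero(~np.isin(arr, (0, 1)))[0])
                raise ValidationError(
                    f"alarm column {k!r} has non-binary value at timestamp {bad + 1}"
                )
            coerced[k] = arr.astype(np.int8)
        self.alarms = coerced

    @property
    def duration(self) -> int:
        return len(next(iter(self.tracks.values())))

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(1, self.duration + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScenarioScript):
            return NotImplemented
        if set(self.tracks) != set(other.tracks) or set(self.alarms) != set(other.alarms):
            return False
        return all(np.array_equal(self.tracks[k], other.tracks[k]) for k in self.tracks) and all(
            np.array_equal(self.alarms[k], other.alarms[k]) for k in self.alarms
        )

    def to_frame(self) -> pd.DataFrame:
        """The file layout: ``t``, parameter columns, then alarm columns."""
        data: Dict[str, np.ndarray] = {"t": self.timestamps}
        data.update(self.tracks)
        data.update({k: v.astype(int) for k, v in self.alarms.items()})
        return pd.DataFrame(data)


def assemble_script(
    tracks: Mapping[str, Sequence[float]],
    duration_s: int,
    alarm_ids: Iterable[str] = (),
) -> ScenarioScript:
    """Combine parameter tracks into a script with all-zero alarm columns.

    Alarm columns listed in ``alarm_ids`` are created in the off state;
    :func:`evaluate_alarms` fills them in from a rule set.
    """
    if duration_s < 1:
        raise DomainError(f"duration_s must be >= 1, got {duration_s}")
    for name, values in tracks.items():
        if len(values) != duration_s:
            raise LengthMismatchError(
                f"track {name!r} has length {len(values)}, expected {duration_s}"
            )
    alarms = {aid: np.zeros(duration_s, dtype=np.int8) for aid in alarm_ids}
    return ScenarioScript(tracks=dict(tracks), alarms=alarms)


def evaluate_alarms(
    script: ScenarioScript,
    rules: Sequence[AlarmRule],
    latching: bool = False,
) -> ScenarioScript:
    """Recompute every alarm column from the parameter tracks and rule set.

    The result's alarm columns are exactly the alarm IDs of ``rules``;
    several rules may share an ID (e.g. HR-low and HR-high both map to the
    cardiac alarm), in which case the column is the logical OR of their
    conditions.  With ``latching=True`` an alarm stays on once triggered.
    """
    validate_rule_set(rules)
    for r in rules:
        if r.parameter not in script.tracks:
            raise SchemaError(f"rule references unknown parameter {r.parameter!r}")
    n = script.duration
    states: Dict[str, np.ndarray] = {r.alarm_id: np.zeros(n, dtype=bool) for r in rules}
    for r in rules:
        states[r.alarm_id] |= r.condition(script.tracks[r.parameter])
    if latching:
        states = {k: np.maximum.accumulate(v) for k, v in states.items()}
    return ScenarioScript(
        tracks={k: v.copy() for k, v in script.tracks.items()},
        alarms={k: v.astype(np.int8) for k, v in states.items()},
    )


def first_alarm_time(script: ScenarioScript, alarm_id: str) -> Optional[int]:
    """Smallest timestamp at which ``alarm_id`` annunciates, or ``None``."""
    if alarm_id not in script.alarms:
        raise SchemaError(f"unknown alarm id {alarm_id!r}")
    on = np.flatnonzero(script.alarms[alarm_id])
    return int(on[0]) + 1 if on.size else None


# ---------------------------------------------------------------------------
# File I/O.  Layout: header row "t", parameter names, alarm IDs; one data row
# per second.  CSV (UTF-8) and XLSX carry the identical column layout.
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "xlsx"):
            raise DomainError(f"dialect must be 'csv' or 'xlsx', got {dialect!r}")
        return dialect
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "xlsx"):
        return suffix
    raise DomainError(f"cannot infer dialect from {path.name!r}; pass dialect=")


def write_script(
    script: ScenarioScript,
    path: str | Path,
    dialect: Optional[str] = None,
    bounds: Optional[Mapping[str, tuple[float, float]]] = PARAMETER_BOUNDS,
) -> Path:
    """Write a script to CSV or XLSX, enforcing per-parameter range checks.

    ``bounds`` maps parameter name to (min, max); pass ``None`` to skip the
    physiological range check.
    """
    path = Path(path)
    if bounds:
        for name, values in script.tracks.items():
            if name in bounds:
                lo, hi = bounds[name]
                bad = np.flatnonzero((values < lo) | (values > hi))
                if bad.size:
                    t = int(bad[0]) + 1
                    raise ValidationError(
                        f"track {name!r} out of range [{lo}, {hi}] at timestamp {t} "
                        f"(value {values[bad[0]]})"
                    )
    frame = script.to_frame()
    if _infer_dialect(path, dialect) == "csv":
        frame.to_csv(path, index=False)
    else:
        frame.to_excel(path, index=False, engine="openpyxl")
    return path


def read_script(
    path: str | Path,
    dialect: Optional[str] = None,
    parameters: Sequence[str] = PARAMETER_VOCABULARY,
) -> ScenarioScript:
    """Read a script file, validating layout, timestamps, and alarm cells.

    Columns whose names are in ``parameters`` become tracks; every other
    column (besides ``t``) is treated as an alarm column and must be binary.
    """
    path = Path(path)
    if _infer_dialect(path, dialect) == "csv":
        frame = pd.read_csv(path)
    else:
        frame = pd.read_excel(path, engine="openpyxl")
    if frame.columns[0] != "t":
        raise ValidationError(
            f"malformed header: first column must be 't', got {frame.columns[0]!r}"
        )
    t = frame["t"].to_numpy()
    expected = np.arange(1, len(frame) + 1)
    if not np.array_equal(t, expected):
        bad = int(np.flatnonzero(t != expected)[0])
        raise ValidationError(
            f"non-consecutive timestamps at data row {bad + 1}: got {t[bad]}"
        )
    tracks: Dict[str, np.ndarray] = {}
    alarms: Dict[str, np.ndarray] = {}
    for col in frame.columns[1:]:
        values = frame[col].to_numpy()
        if col in parameters:
            tracks[col] = np.asarray(values, dtype=float)
        else:
            arr = np.asarray(values)
            bad = np.flatnonzero(~np.isin(arr, (0, 1)))
            if bad.size:
                raise ValidationError(
                    f"non-binary alarm cell in column {col!r} at data row "
                    f"{int(bad[0]) + 1}: got {arr[bad[0]]}"
                )
            alarms[col] = arr.astype(np.int8)
    if not tracks:
        raise ValidationError("no recognised parameter columns in file")
    return ScenarioScript(tracks=tracks, alarms=alarms)


# ---------------------------------------------------------------------------
# Rule-set configuration
# ---------------------------------------------------------------------------

def load_rules(source: str | Path | Mapping) -> tuple[list[AlarmRule], bool]:
    """Load a threshold rule set from a YAML/JSON-style mapping or file.

    Returns ``(rules, latching)``.  Expected shape::

        latching: false
        rules:
          - {parameter: HR, direction: low, threshold: 60,
             priority: medium, alarm_id: cardmed}
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, Mapping) or "rules" not in source:
        raise ValidationError("rule config must be a mapping with a 'rules' list")
    rules = [AlarmRule(**entry) for entry in source["rules"]]
    validate_rule_set(rules)
    return rules, bool(source.get("latching", False))


def default_rules() -> tuple[list[AlarmRule], bool]:
    """The shipped adult-patient alarm threshold defaults (editable YAML)."""
    ref = resources.files("orsim.data").joinpath("alarm_rules.yaml")
    return load_rules(yaml.safe_load(ref.read_text(encoding="utf-8")))
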