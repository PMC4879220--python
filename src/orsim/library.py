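"""Parameterized generators for the scenario library.

The library ships two uneventful and two eventful 30-minute scripts.  Each
eventful script carries three intraoperative events, one per ten-minute
window, defined as piecewise-linear excursions of parameter tracks away from
(and back to) baseline.  Event shapes, amplitudes and timings live in an
editable YAML config (``orsim/data/scenarios.yaml``); generation is fully
deterministic given ``(name, config)``.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import DomainError, SchemaError
from .scenario import (
    AlarmRule,
    ScenarioScript,
    assemble_script,
    default_rules,
    evaluate_alarms,
)

__all__ = [
    "EVENT_KINDS",
    "Excursion",
    "EventTemplate",
    "EventRecord",
    "default_config",
    "load_config",
    "build_baseline",
    "make_event_tracks",
    "make_scenario",
    "write_manifest",
    "read_manifest",
]

EVENT_KINDS = (
    "circuit_disconnect",
    "symptomatic_bradycardia",
    "endobronchial_migration",
    "hypovolemia",
    "pulmonary_embolism",
    "light_anesthesia",
    "uneventful",
)

SCENARIO_NAMES = ("uneventful_1", "uneventful_2", "eventful_1", "eventful_2")


@dataclass(frozen=True)
class Excursion:
    """One parameter's linear departure from baseline and return.

    ``onset`` is the absolute timestamp of the last second still at baseline;
    the value ramps to ``target`` over ``ramp_up`` s, holds ``hold`` s, and
    ramps back over ``ramp_down`` s, reaching baseline again exactly at
    ``onset + ramp_up + hold + ramp_down``.
    """

    parameter: str
    onset: int
    ramp_up: int
    hold: int
    ramp_down: int
    target: float

    @property
    def end(self) -> int:
        return self.onset + self.ramp_up + self.hold + self.ramp_down


@dataclass
class EventTemplate:
    kind: str
    window: tuple[int, int]  # inclusive [start, end] timestamps
    excursions: List[Excursion]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise DomainError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class EventRecord:
    """Manifest entry: where an event actually perturbs the script."""

    kind: str
    window: tuple[int, int]
    onset: Optional[int]  # first second any track differs from baseline
    offset: Optional[int]  # last such second


def default_config() -> dict:
    ref = resources.files("orsim.data").joinpath("scenarios.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def build_baseline(config: Optional[Mapping] = None, duration_s: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Constant normal-vitals tracks for every configured parameter."""
    cfg = config if config is not None else default_config()
    n = int(duration_s if duration_s is not None else cfg["duration_s"])
    if n < 1:
        raise DomainError("duration must be >= 1 s")
    return {name: np.full(n, float(v)) for name, v in cfg["baseline"].items()}


def _derive_crossing_onset(baseline: float, target: float, ramp_up: int, threshold: float, at: int) -> int:
    """Onset such that the linear ramp first passes strictly beyond
    ``threshold`` exactly at timestamp ``at``."""
    if ramp_up < 1 or (baseline - target) == 0:
        raise DomainError("crossing anchor needs a non-degenerate ramp")
    frac = (baseline - threshold) / (baseline - target)
    if not 0.0 < frac < 1.0:
        raise DomainError(
            f"threshold {threshold} not strictly between baseline {baseline} and target {target}"
        )
    j = math.floor(frac * ramp_up) + 1  # first integer step strictly past threshold
    return at - j


def resolve_event(kind: str, window: tuple[int, int], config: Optional[Mapping] = None) -> EventTemplate:
    """Turn a config entry into an :class:`EventTemplate` with absolute onsets."""
    cfg = config if config is not None else default_config()
    if kind == "uneventful":
        return EventTemplate(kind=kind, window=window, excursions=[])
    try:
        entry = cfg["events"][kind]
    except KeyError:
        raise SchemaError(f"no config for event kind {kind!r}") from None
    excursions: List[Excursion] = []
    for exc in entry["excursions"]:
        exc = dict(exc)
        crossing = exc.pop("crossing", None)
        if crossing is not None:
            base = float(cfg["baseline"][exc["parameter"]])
            onset = _derive_crossing_onset(
                base, float(exc["target"]), int(exc["ramp_up"]),
                float(crossing["threshold"]), int(crossing["at"]),
            )
        else:
            onset = window[0] - 1 + int(exc.pop("onset"))
        exc.pop("onset", None)
        excursions.append(Excursion(onset=onset, **exc))
    return EventTemplate(kind=kind, window=window, excursions=excursions)


def _apply_excursion(values: np.ndarray, exc: Excursion) -> None:
    b = float(values[exc.onset - 1]) if exc.onset >= 1 else float(values[0])
    for j in range(1, exc.ramp_up + 1):
        values[exc.onset + j - 1] = b + (exc.target - b) * j / exc.ramp_up
    lo = exc.onset + exc.ramp_up
    values[lo : lo + exc.hold] = exc.target
    lo = exc.onset + exc.ramp_up + exc.hold
    for j in range(1, exc.ramp_down + 1):
        values[lo + j - 1] = exc.target + (b - exc.target) * j / exc.ramp_down


def make_event_tracks(
    template: EventTemplate,
    baseline: Mapping[str, np.ndarray],
) -> Dict[str, np.ndarray]:
    """Apply one event's excursions to baseline tracks.

    Outside the event window the output equals the baseline; every affected
    parameter returns to its baseline value before the window ends.
    """
    n = len(next(iter(baseline.values())))
    tracks = {k: np.asarray(v, dtype=float).copy() for k, v in baseline.items()}
    lo_w, hi_w = template.window
    if not (1 <= lo_w <= hi_w <= n):
        raise DomainError(f"window {template.window} does not fit a {n}-second script")
    for exc in template.excursions:
        if exc.parameter not in tracks:
            raise SchemaError(f"excursion references unknown parameter {exc.parameter!r}")
        if min(exc.ramp_up, exc.hold, exc.ramp_down) < 0:
            raise DomainError("ramp/hold durations must be non-negative")
        if exc.onset < lo_w - 1 or exc.end > hi_w:
            raise DomainError(
                f"{template.kind}/{exc.parameter}: excursion [{exc.onset + 1}, {exc.end}] "
                f"overflows window {template.window}"
            )
        _apply_excursion(tracks[exc.parameter], exc)
    return tracks


def _diff_interval(
    tracks: Mapping[str, np.ndarray],
    baseline: Mapping[str, np.ndarray],
    window: tuple[int, int],
) -> tuple[Optional[int], Optional[int]]:
    lo, hi = window
    diff = np.zeros(hi - lo + 1, dtype=bool)
    for k in tracks:
        diff |= tracks[k][lo - 1 : hi] != baseline[k][lo - 1 : hi]
    idx = np.flatnonzero(diff)
    if not idx.size:
        return None, None
    return lo + int(idx[0]), lo + int(idx[-1])


def make_scenario(
    name: str,
    config: Optional[Mapping] = None,
    rules: Optional[Sequence[AlarmRule]] = None,
    latching: Optional[bool] = None,
) -> tuple[ScenarioScript, List[EventRecord]]:
    """Generate one library scenario: an alarm-evaluated script + manifest.

    ``name`` is one of ``uneventful_1``, ``uneventful_2``, ``eventful_1``,
    ``eventful_2`` (extra names may be defined in a custom config).  The
    manifest records, for each scripted event, the window and the actual
    first/last seconds at which any track departs from baseline.
    """
    cfg = copy.deepcopy(config) if config is not None else default_config()
    if name not in cfg.get("scenarios", {}):
        raise DomainError(f"unknown scenario {name!r}; known: {sorted(cfg['scenarios'])}")
    if rules is None or latching is None:
        d_rules, d_latch = default_rules()
        rules = d_rules if rules is None else rules
        latching = d_latch if latching is None else latching
    duration = int(cfg["duration_s"])
    windows = [tuple(w) for w in cfg["windows"]]
    kinds = cfg["scenarios"][name]
    if len(kinds) > len(windows):
        raise DomainError(f"{name}: more events than windows")
    baseline = build_baseline(cfg, duration)
    tracks = {k: v.copy() for k, v in baseline.items()}
    manifest: List[EventRecord] = []
    for window, kind in zip(windows, kinds):
        template = resolve_event(kind, window, cfg)
        tracks = make_event_tracks(template, tracks)
        onset, offset = _diff_interval(tracks, baseline, window)
        manifest.append(EventRecord(kind=kind, window=window, onset=onset, offset=offset))
    script = assemble_script(tracks, duration)
    script = evaluate_alarms(script, rules, latching=latching)
    return script, manifest


def write_manifest(manifest: Sequence[EventRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([asdict(rec) for rec in manifest], fh, indent=2)
    return path


def read_manifest(path: str | Path) -> List[EventRecord]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        EventRecord(
            kind=rec["kind"],
            window=tuple(rec["window"]),
            onset=rec["onset"],
            offset=rec["offset"],
        )
        for rec in raw
    ]
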