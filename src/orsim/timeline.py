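"""Blinded-rating timelines (three-band stem plots) and response latencies.

Raters assess a subject from a timeline with three vertically separated
bands: (top) the scripted state changes and alarm annunciations, identical
for every subject on the same scenario; (middle) the subject's own
timestamped entries; (bottom) cohort-average times to detection,
differential, and intervention for each event.  The vertical coordinate has
no quantitative meaning — only band membership and time matter.

Latency for a (subject, event, category) is the time from event onset to the
subject's *first* entry of that category inside the event window; subjects
with no qualifying entry are counted as misses and excluded from means
rather than imputed (misses are scored separately by the checklist).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .library import EventRecord
from .playback import SessionLog
from .scenario import ScenarioScript

__all__ = ["TimelineBundle", "build_timeline", "latency_summary", "render_stem_plot"]

_LATENCY_CATEGORIES = ("detection", "differential", "intervention")


@dataclass
class TimelineBundle:
    """Serializable data behind one subject's three-band stem plot."""

    scenario: str
    subject_id: str  # opaque code; no identity beyond this
    band_events: List[dict] = field(default_factory=list)   # {"t", "label", "kind"}
    band_subject: List[dict] = field(default_factory=list)  # {"t", "category", "text"}
    band_cohort: List[dict] = field(default_factory=list)   # {"event", "category", "mean_t", "n", "misses"}

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TimelineBundle":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _event_band(script: ScenarioScript, manifest: Sequence[EventRecord]) -> List[dict]:
    band: List[dict] = []
    for rec in manifest:
        if rec.onset is not None:
            band.append({"t": int(rec.onset), "label": f"{rec.kind} onset", "kind": "state_change"})
            band.append({"t": int(rec.offset), "label": f"{rec.kind} resolved", "kind": "state_change"})
    for alarm_id, states in script.alarms.items():
        onsets = np.flatnonzero(np.diff(np.concatenate([[0], states])) == 1)
        for idx in onsets:
            band.append({"t": int(idx) + 1, "label": f"alarm {alarm_id}", "kind": "alarm"})
    return sorted(band, key=lambda d: d["t"])


def latency_summary(
    logs: Sequence[SessionLog],
    manifest: Sequence[EventRecord],
) -> pd.DataFrame:
    """Per-event mean first-response latencies for detection / differential /
    intervention.

    Returns a DataFrame indexed by (event, category) with columns
    ``mean_latency``, ``n`` (subjects contributing), and ``misses``.
    """
    if not logs:
        raise DomainError("latency summary needs at least one session log")
    rows = []
    for rec in manifest:
        if rec.onset is None:
            continue
        lo, hi = rec.window
        for category in _LATENCY_CATEGORIES:
            latencies = []
            misses = 0
            for log in logs:
                hits = [e.t for e in log.entries if e.category == category and lo <= e.t <= hi]
                if hits:
                    latencies.append(min(hits) - rec.onset)
                else:
                    misses += 1
            rows.append(
                {
                    "event": rec.kind,
                    "category": category,
                    "mean_latency": float(np.mean(latencies)) if latencies else float("nan"),
                    "n": len(latencies),
                    "misses": misses,
                }
            )
    return pd.DataFrame(rows, columns=["event", "category", "mean_latency", "n", "misses"]).set_index(
        ["event", "category"]
    )


def build_timeline(
    log: SessionLog,
    script: ScenarioScript,
    cohort: Sequence[SessionLog],
    manifest: Optional[Sequence[EventRecord]] = None,
) -> TimelineBundle:
    """Assemble the three bands for one subject.

    ``band_events`` depends only on (script, manifest) and is therefore
    identical across subjects; ``band_cohort`` holds cohort-mean absolute
    response times (event onset + mean latency) per event and category.
    """
    if manifest is None:
        manifest = log.manifest
    if manifest is None:
        raise DomainError("an event manifest is required (log.manifest or manifest=)")
    for other in cohort:
        if other.scenario != log.scenario:
            raise DomainError(
                f"cohort log for scenario {other.scenario!r} mixed into {log.scenario!r}"
            )
    summary = latency_summary(list(cohort) or [log], manifest)
    onsets = {rec.kind: rec.onset for rec in manifest if rec.onset is not None}
    cohort_band = []
    for (event, category), row in summary.iterrows():
        if row["n"] > 0:
            cohort_band.append(
                {
                    "event": event,
                    "category": category,
                    "mean_t": float(onsets[event] + row["mean_latency"]),
                    "n": int(row["n"]),
                    "misses": int(row["misses"]),
                }
            )
    return TimelineBundle(
        scenario=log.scenario,
        subject_id=log.subject_id,
        band_events=_event_band(script, manifest),
        band_subject=[
            {"t": e.t, "category": e.category, "text": e.text} for e in log.entries
        ],
        band_cohort=cohort_band,
    )


_CATEGORY_COLORS = {
    "detection": "tab:blue",
    "differential": "tab:green",
    "intervention": "tab:purple",
    "distractor_answer": "tab:gray",
    "other": "tab:brown",
}


def render_stem_plot(bundle: TimelineBundle, path: str | Path, dpi: int = 110) -> Path:
    """Render the three-band stem plot to PNG or SVG.

    The y axis only separates the bands (events ≈ 3, subject ≈ 2, cohort ≈ 1)
    and is hidden; markers follow the band conventions: red diamonds/squares
    for scripted events and alarms, category-coloured circles for subject
    entries, red triangles for cohort means.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(11, 4))
    for item in bundle.band_events:
        marker = "D" if item["kind"] == "state_change" else "s"
        ax.stem([item["t"]], [3.0], linefmt="r-", basefmt=" ", markerfmt="r" + marker)
        ax.annotate(item["label"], (item["t"], 3.0), rotation=60, fontsize=6,
                    xytext=(0, 4), textcoords="offset points")
    seen = set()
    for item in bundle.band_subject:
        color = _CATEGORY_COLORS.get(item["category"], "k")
        label = item["category"] if item["category"] not in seen else None
        seen.add(item["category"])
        ax.stem([item["t"]], [2.0], linefmt=color, basefmt=" ", markerfmt="o")
        ax.plot([item["t"]], [2.0], "o", color=color, label=label)
    for item in bundle.band_cohort:
        ax.stem([item["mean_t"]], [1.0], linefmt="r:", basefmt=" ", markerfmt="r^")
    ax.plot([], [], "rD", label="scripted events / alarms")
    ax.plot([], [], "r^", label="cohort mean responses")
    ax.set_ylim(0, 4)
    ax.set_yticks([])
    ax.set_xlabel("scenario time [s]")
    ax.set_title(f"{bundle.scenario} — subject {bundle.subject_id}")
    ax.legend(loc="upper right", fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=dpi, metadata=_stable_metadata(path))
    plt.close(fig)
    return path


def _stable_metadata(path: Path) -> Optional[dict]:
    # strip volatile timestamps so identical bundles render byte-identical files
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    if path.suffix.lower() == ".png":
        return {"Software": "orsim"}
    return None
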