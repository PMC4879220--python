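"""Synthetic raters and responders with known ground-truth structure.

The generators let every pipeline stage be exercised without human data:

* :func:`generate_rating_table` draws two-rater rating tables from a
  classical true-score model — each subject×scenario cell has a latent
  ability ``a ~ N(0, σ_T)`` shared by all items, and each rater carries a
  holistic per-cell error ``e_r ~ N(0, σ_E)`` (plus an optional per-item
  jitter σ_item); the observed item score is
  ``clamp(round(item_center + a + bias_r + e_r + jitter))``.  The implied
  continuous-scale consistency ICC is σ²_T/(σ²_T+σ²_E) at both the item and
  the instrument-total level; discretization to the Likert/trichotomous
  scale attenuates estimates slightly.
* :func:`generate_session_logs` emits per-subject response streams: for each
  scripted event, with probability (1 − miss), a detection entry at
  onset + latency, followed by differential and intervention entries, plus
  uniformly scattered distractor answers.

Seeds are mandatory; no global random state is touched, and the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .instruments import (
    CMC_ITEMS,
    CMC_NEGATIVE_ITEMS,
    GRS_ITEMS,
    RATING_COLUMNS,
    items_for,
)
from .library import EventRecord
from .playback import ResponseEntry, SessionLog

__all__ = [
    "RaterModel",
    "ResponderModel",
    "generate_rating_table",
    "generate_session_logs",
    "DEFAULT_SCENARIOS",
]

#: The six emergency scenarios a subject is rated on (one per event).
DEFAULT_SCENARIOS: Tuple[str, ...] = (
    "circuit_disconnect",
    "symptomatic_bradycardia",
    "endobronchial_migration",
    "hypovolemia",
    "pulmonary_embolism",
    "light_anesthesia",
)


@dataclass(frozen=True)
class RaterModel:
    """True-score model for a pair of raters.

    ``sigma_true`` and ``sigma_err`` are standard deviations of the latent
    ability and of each rater's observation noise, on the instrument's raw
    item scale; ``biases`` are per-rater additive offsets.  The implied
    continuous-scale consistency ICC is σ²_T/(σ²_T+σ²_E).
    """

    sigma_true: float
    sigma_err: float
    biases: Tuple[float, ...] = (0.0, 0.0)
    sigma_item: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_true < 0 or self.sigma_err < 0 or self.sigma_item < 0:
            raise DomainError("model standard deviations must be non-negative")
        if len(self.biases) < 2:
            raise DomainError("need at least two raters")

    @property
    def true_icc(self) -> float:
        denom = self.sigma_true**2 + self.sigma_err**2
        return self.sigma_true**2 / denom if denom > 0 else float("nan")

    @classmethod
    def from_icc(
        cls,
        icc: float,
        total_sd: float = 1.5,
        biases: Tuple[float, ...] = (0.0, 0.0),
    ) -> "RaterModel":
        """Split a target consistency ICC into (σ_T, σ_E) at a given total
        continuous-scale SD."""
        if not 0.0 <= icc <= 1.0:
            raise DomainError(f"icc must be in [0, 1], got {icc}")
        var = total_sd**2
        return cls(
            sigma_true=float(np.sqrt(icc * var)),
            sigma_err=float(np.sqrt((1.0 - icc) * var)),
            biases=biases,
        )


def _item_scales(instrument: str) -> Dict[str, Tuple[float, int, int]]:
    """item -> (center, lo, hi) on the raw discrete scale."""
    if instrument == "grs":
        return {item: (4.0, 1, 7) for item in GRS_ITEMS}
    scales: Dict[str, Tuple[float, int, int]] = {}
    for item in CMC_ITEMS:
        if item in CMC_NEGATIVE_ITEMS:
            scales[item] = (-1.0, -2, 0)
        else:
            scales[item] = (1.0, 0, 2)
    return scales


def generate_rating_table(
    model: RaterModel,
    n_subjects: int,
    n_scenarios: int,
    instrument: str,
    seed: int,
    scenarios: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Draw a reproducible long-format two-rater rating table.

    With ``sigma_err=0`` and zero biases the two raters agree exactly.
    Scenario names default to the six library events (cycled if
    ``n_scenarios`` exceeds six).
    """
    if n_subjects < 1 or n_scenarios < 1:
        raise DomainError("n_subjects and n_scenarios must be >= 1")
    items = items_for(instrument)
    scales = _item_scales(instrument)
    if scenarios is None:
        scenarios = [DEFAULT_SCENARIOS[i % len(DEFAULT_SCENARIOS)] if n_scenarios <= len(DEFAULT_SCENARIOS)
                     else f"scenario_{i + 1}" for i in range(n_scenarios)]
    else:
        scenarios = list(scenarios)
        if len(scenarios) != n_scenarios:
            raise DomainError("scenarios list must have length n_scenarios")
    rng = np.random.default_rng(seed)
    n_raters = len(model.biases)
    rows: List[dict] = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for scen in scenarios:
            ability = rng.normal(0.0, model.sigma_true)
            rater_err = [
                rng.normal(0.0, model.sigma_err) if model.sigma_err > 0 else 0.0
                for _ in range(n_raters)
            ]
            for item in items:
                center, lo, hi = scales[item]
                true_score = center + ability
                for r in range(n_raters):
                    jitter = rng.normal(0.0, model.sigma_item) if model.sigma_item > 0 else 0.0
                    raw = true_score + model.biases[r] + rater_err[r] + jitter
                    score = int(np.clip(np.rint(raw), lo, hi))
                    rows.append(
                        {
                            "rater_id": f"R{r + 1}",
                            "subject_id": subject,
                            "scenario": scen,
                            "instrument": instrument,
                            "item": item,
                            "score": score,
                        }
                    )
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


@dataclass(frozen=True)
class ResponderModel:
    """Stochastic subject behaviour during a scripted scenario.

    ``latency_mean``/``latency_sd`` give Normal latency parameters [s] for
    each response category, applied sequentially (differential follows the
    detection entry, intervention follows the differential).  ``miss_prob``
    is the probability an event goes entirely unanswered; ``distractor_rate``
    is the expected number of distractor answers per minute.
    """

    latency_mean: Mapping[str, float] = field(
        default_factory=lambda: {"detection": 60.0, "differential": 90.0, "intervention": 120.0}
    )
    latency_sd: Mapping[str, float] = field(
        default_factory=lambda: {"detection": 10.0, "differential": 20.0, "intervention": 30.0}
    )
    miss_prob: float = 0.1
    distractor_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise DomainError("miss_prob must be in [0, 1]")
        if self.distractor_rate < 0:
            raise DomainError("distractor_rate must be non-negative")
        for cat in ("detection", "differential", "intervention"):
            if cat not in self.latency_mean or cat not in self.latency_sd:
                raise DomainError(f"latency parameters missing for {cat!r}")


_TEXT_TEMPLATES = {
    "detection": "noticed {kind} state change",
    "differential": "differential: suspect {kind}",
    "intervention": "intervention for {kind} started",
}


def generate_session_logs(
    model: ResponderModel,
    manifest: Sequence[EventRecord],
    n_subjects: int,
    seed: int,
    duration_s: int = 1800,
    scenario: str = "",
) -> List[SessionLog]:
    """Simulate ``n_subjects`` response streams against one event manifest.

    Entries that would fall beyond the scenario end are clipped to the final
    second and marked ``[clipped]`` in their text.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    logs: List[SessionLog] = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        entries: List[ResponseEntry] = []
        for rec in manifest:
            if rec.onset is None:
                continue
            if rng.random() < model.miss_prob:
                continue
            t = float(rec.onset)
            for category in ("detection", "differential", "intervention"):
                lat = rng.normal(model.latency_mean[category], model.latency_sd[category])
                t = t + max(lat, 0.0)
                tt = int(round(t))
                clipped = tt > duration_s
                tt = min(max(tt, 1), duration_s)
                text = _TEXT_TEMPLATES[category].format(kind=rec.kind)
                if clipped:
                    text += " [clipped]"
                entries.append(
                    ResponseEntry(t=tt, subject_id=subject, text=text, category=category)
                )
        n_distractors = rng.poisson(model.distractor_rate * duration_s / 60.0)
        for t in sorted(rng.integers(1, duration_s + 1, size=n_distractors)):
            entries.append(
                ResponseEntry(
                    t=int(t),
                    subject_id=subject,
                    text="distractor answer",
                    category="distractor_answer",
                )
            )
        logs.append(
            SessionLog(
                scenario=scenario,
                subject_id=subject,
                entries=entries,
                manifest=list(manifest),
            )
        )
    return logs
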