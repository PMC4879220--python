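"""Reliability and validity statistics for the rating instruments.

Implements the validation pipeline end to end:

* internal consistency — Cronbach's α and corrected item-total analysis on
  the rater-averaged item matrix;
* interrater reliability — two-way single-measure intraclass correlations
  from ANOVA mean squares, in both the *consistency* variant ICC(3,1),
  which ignores systematic rater offsets, and the *absolute agreement*
  variant ICC(2,1), which penalizes them, with F tests and significance
  flags;
* convergent validity — Spearman rank correlation between instruments;
* effect-size summaries — median-split / quartile-split / scenario-contrast
  group means with raw difference, percent difference, and Cohen's d.

Conventions: all variances use ddof=1; the significance flag threshold is
p > 0.05; no multiple-testing correction is applied; cells that cannot be
computed (zero variance) carry an ``incalculable_zero_variance`` flag rather
than a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .instruments import (
    CMC_LOW_DISCRIMINATION_ITEMS,
    CMC_SUBSCALES,
    items_for,
    rating_totals,
    validate_rating_table,
)

__all__ = [
    "ICCResult",
    "CorrelationResult",
    "ReliabilityReport",
    "cronbach_alpha",
    "item_total_analysis",
    "icc",
    "spearman",
    "rater_average_matrix",
    "reliability_report",
    "effect_size_table",
]

ALPHA_LEVEL = 0.05

FLAG_NOT_SIGNIFICANT = "not_significant"
FLAG_INCALCULABLE = "incalculable_zero_variance"
FLAG_NEGATIVE = "negative"


# ---------------------------------------------------------------------------
# Internal consistency
# ---------------------------------------------------------------------------

def _as_matrix(items_matrix) -> np.ndarray:
    X = np.asarray(items_matrix, dtype=float)
    if X.ndim != 2:
        raise DomainError("items matrix must be 2-D (observations × items)")
    if not np.all(np.isfinite(X)):
        raise DomainError("items matrix contains non-finite values")
    return X


def cronbach_alpha(items_matrix) -> float:
    """Cronbach's α = k/(k−1) · (1 − Σ σ²_item / σ²_total).

    ``items_matrix`` is observations × items.  Sample variances (ddof=1).
    Returns NaN when the total score has zero variance (incalculable);
    α can legitimately be negative.
    """
    X = _as_matrix(items_matrix)
    n, k = X.shape
    if k < 2:
        raise DomainError(f"need at least 2 items, got {k}")
    if n < 2:
        raise DomainError(f"need at least 2 observations, got {n}")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def item_total_analysis(
    items_matrix, item_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Corrected item-total correlations and α-if-item-deleted.

    The corrected correlation for item *i* is the Pearson r between the item
    and the sum of the *other* items; a constant item yields NaN.  The
    returned frame is indexed by item name with columns
    ``corrected_item_total_r`` and ``alpha_if_deleted``.
    """
    X = _as_matrix(items_matrix)
    n, k = X.shape
    if k < 3:
        raise DomainError(f"item-total analysis needs at least 3 items, got {k}")
    names = list(item_names) if item_names is not None else [f"item_{i}" for i in range(k)]
    if len(names) != k:
        raise DomainError("item_names length must match the number of items")
    rows = []
    for i in range(k):
        rest = X.sum(axis=1) - X[:, i]
        if X[:, i].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(X[:, i], rest)[0, 1])
        rows.append(
            {
                "item": names[i],
                "corrected_item_total_r": r,
                "alpha_if_deleted": cronbach_alpha(np.delete(X, i, axis=1)),
            }
        )
    return pd.DataFrame(rows).set_index("item")


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    estimate: float  # NaN when incalculable
    variant: str     # "consistency" | "absolute_agreement"
    n: int
    k: int
    F: float
    df1: int
    df2: int
    p: float
    flags: Tuple[str, ...] = ()

    @property
    def incalculable(self) -> bool:
        return FLAG_INCALCULABLE in self.flags


def icc(two_rater_table, variant: str = "consistency") -> ICCResult:
    """Two-way single-measure intraclass correlation from ANOVA mean squares.

    ``two_rater_table`` is observations × raters (k ≥ 2 columns).  With
    between-rows mean square MSR, between-columns MSC and residual MSE:

    * ``consistency``        (MSR − MSE) / (MSR + (k−1)·MSE)
    * ``absolute_agreement`` (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    The F test is F = MSR/MSE on (n−1, (n−1)(k−1)) df.  Estimates may be
    negative.  When every response is identical (no variance anywhere) the
    result carries the ``incalculable_zero_variance`` flag and a NaN
    estimate, mirroring the dagger cells of all-zero checklist items.
    """
    if variant not in ("consistency", "absolute_agreement"):
        raise DomainError(f"unknown ICC variant {variant!r}")
    X = _as_matrix(two_rater_table)
    n, k = X.shape
    if n < 2:
        raise DomainError(f"ICC needs at least 2 observations, got {n}")
    if k < 2:
        raise DomainError(f"ICC needs at least 2 raters, got {k}")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    msr = ss_rows / df1
    msc = ss_cols / (k - 1)
    mse = ss_err / df2

    flags: List[str] = []
    if ss_total == 0:
        return ICCResult(float("nan"), variant, n, k, float("nan"), df1, df2,
                         float("nan"), (FLAG_INCALCULABLE,))
    if variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return ICCResult(float("nan"), variant, n, k, float("nan"), df1, df2,
                         float("nan"), (FLAG_INCALCULABLE,))
    estimate = (msr - mse) / denom

    if mse == 0:
        F = float("inf")
        p = 0.0 if msr > 0 else float("nan")
    else:
        F = msr / mse
        p = float(stats.f.sf(F, df1, df2))
    if estimate < 0:
        flags.append(FLAG_NEGATIVE)
    if not (p <= ALPHA_LEVEL):
        flags.append(FLAG_NOT_SIGNIFICANT)
    return ICCResult(float(estimate), variant, n, k, float(F), df1, df2, float(p), tuple(flags))


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    flags: Tuple[str, ...] = ()


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson r of midrank-tied average ranks.

    p-values follow the standard t-approximation used by
    :func:`scipy.stats.spearmanr`.  A constant input vector makes ranks
    degenerate; the result is then flagged incalculable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise DomainError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), (FLAG_INCALCULABLE,))
    res = stats.spearmanr(x, y)
    flags: Tuple[str, ...] = ()
    if not (res.pvalue <= ALPHA_LEVEL):
        flags = (FLAG_NOT_SIGNIFICANT,)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), flags)


# ---------------------------------------------------------------------------
# Full reliability report
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """Machine-readable reliability tables for one instrument.

    ``icc_table`` is long-format with one row per (scope, name, scenario,
    item set, variant); ``item_stats`` carries the internal-consistency
    columns computed on the rater-averaged item matrix.
    """

    instrument: str
    grouping: str
    alpha: float
    alpha_without_exclusions: float
    item_stats: pd.DataFrame
    icc_table: pd.DataFrame
    exclusions: Tuple[str, ...]
    n_raters: int = 2

    def to_json_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "grouping": self.grouping,
            "alpha": None if math.isnan(self.alpha) else self.alpha,
            "alpha_without_exclusions": (
                None if math.isnan(self.alpha_without_exclusions) else self.alpha_without_exclusions
            ),
            "exclusions": list(self.exclusions),
            "item_stats": self.item_stats.reset_index().to_dict(orient="records"),
            "icc": self.icc_table.to_dict(orient="records"),
        }


def rater_average_matrix(
    table: pd.DataFrame, instrument: str, scenario: Optional[str] = None
) -> pd.DataFrame:
    """Rater-averaged item matrix: rows = subject×scenario cells (or
    subjects, for a single scenario), columns = items."""
    sub = table[table["instrument"] == instrument]
    if scenario is not None:
        sub = sub[sub["scenario"] == scenario]
    if sub.empty:
        raise DomainError(f"no ratings for {instrument!r} / scenario {scenario!r}")
    avg = sub.groupby(["subject_id", "scenario", "item"])["score"].mean().reset_index()
    wide = avg.pivot_table(index=["subject_id", "scenario"], columns="item", values="score")
    return wide[list(items_for(instrument))]


def _two_rater_pivot(sub: pd.DataFrame, raters: Sequence, value: str = "score") -> np.ndarray:
    wide = sub.pivot_table(index=["subject_id", "scenario"], columns="rater_id", values=value)
    return wide[list(raters)].to_numpy()


def _icc_rows(
    data: np.ndarray,
    scope: str,
    name: str,
    scenario: str,
    item_set: str,
) -> List[dict]:
    rows = []
    for variant in ("consistency", "absolute_agreement"):
        r = icc(data, variant)
        rows.append(
            {
                "scope": scope,
                "name": name,
                "scenario": scenario,
                "items": item_set,
                "variant": variant,
                "estimate": r.estimate,
                "n": r.n,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "flags": ";".join(r.flags),
            }
        )
    return rows


def reliability_report(
    table: pd.DataFrame,
    instrument: str,
    grouping: str = "all",
    item_exclusions: Optional[Iterable[str]] = None,
) -> ReliabilityReport:
    """Compute the full reliability table set for one instrument.

    ``grouping="all"`` pools subject×scenario cells as independent rows
    (n = subjects × scenarios); ``grouping="scenario"`` additionally reports
    each scenario separately (n = subjects).  ``item_exclusions`` defaults to
    the instrument's flagged low-discrimination items and drives the
    item-removal variants of the subscale/total ICC rows and α.
    """
    validate_rating_table(table)
    sub = table[table["instrument"] == instrument]
    if sub.empty:
        raise DomainError(f"no ratings for instrument {instrument!r}")
    raters = sorted(sub["rater_id"].unique())
    if len(raters) != 2:
        raise DomainError(f"the study design has exactly 2 raters, found {len(raters)}")
    if grouping not in ("all", "scenario"):
        raise DomainError(f"grouping must be 'all' or 'scenario', got {grouping!r}")
    if item_exclusions is None:
        item_exclusions = (
            ("perceived_crisis_resolution",)
            if instrument == "grs"
            else CMC_LOW_DISCRIMINATION_ITEMS
        )
    exclusions = tuple(item_exclusions)
    all_items = items_for(instrument)
    kept_items = tuple(i for i in all_items if i not in exclusions)

    # --- internal consistency on the rater-averaged matrix (aggregate)
    avg = rater_average_matrix(table, instrument)
    alpha = cronbach_alpha(avg.to_numpy())
    item_stats = item_total_analysis(avg.to_numpy(), item_names=list(avg.columns))
    alpha_excl = (
        cronbach_alpha(avg[list(kept_items)].to_numpy()) if len(kept_items) >= 2 else float("nan")
    )

    # --- interrater reliability
    scenario_groups: List[Optional[str]] = [None]
    if grouping == "scenario":
        scenario_groups = sorted(sub["scenario"].unique()) + [None]

    rows: List[dict] = []
    for scen in scenario_groups:
        scen_label = "all" if scen is None else str(scen)
        block = sub if scen is None else sub[sub["scenario"] == scen]
        for item in all_items:
            data = _two_rater_pivot(block[block["item"] == item], raters)
            rows += _icc_rows(data, "item", item, scen_label, "all")
        if instrument == "cmc":
            for subscale, s_items in CMC_SUBSCALES.items():
                for label, use in (
                    ("all", s_items),
                    ("excluding_flagged", tuple(i for i in s_items if i not in exclusions)),
                ):
                    part = block[block["item"].isin(use)]
                    totals = part.groupby(["rater_id", "subject_id", "scenario"])["score"].sum().reset_index()
                    data = _two_rater_pivot(totals, raters, value="score")
                    rows += _icc_rows(data, "subscale", subscale, scen_label, label)
        for label, use in (("all", all_items), ("excluding_flagged", kept_items)):
            part = block[block["item"].isin(use)]
            totals = part.groupby(["rater_id", "subject_id", "scenario"])["score"].sum().reset_index()
            data = _two_rater_pivot(totals, raters, value="score")
            rows += _icc_rows(data, "total", "total", scen_label, label)

    icc_table = pd.DataFrame(rows)
    return ReliabilityReport(
        instrument=instrument,
        grouping=grouping,
        alpha=alpha,
        alpha_without_exclusions=alpha_excl,
        item_stats=item_stats,
        icc_table=icc_table,
        exclusions=exclusions,
        n_raters=len(raters),
    )


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray) -> Tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def effect_size_table(
    subject_means: pd.Series,
    scenario_table: Optional[pd.DataFrame] = None,
    contrast: Optional[Tuple[str, str]] = None,
) -> pd.DataFrame:
    """Group-contrast effect sizes for one instrument.

    ``subject_means`` holds each subject's total score averaged across all
    scenarios; ``scenario_table`` (subjects × scenarios) supplies the
    scenario contrast, whose two groups are the per-subject scores on
    ``contrast[0]`` (group 1) and ``contrast[1]`` (group 2).

    Three splits are reported:

    * ``median_split`` — lower vs upper 50th percentile of subject means;
    * ``quartile_split`` — 2nd vs 3rd quartile;
    * ``scenario_contrast`` — the two named scenarios (if provided).

    For every row: difference = mean2 − mean1; percent difference =
    difference / mean(mean1, mean2) × 100; Cohen's d = difference divided by
    the standard deviation pooled over *all* subject aggregate scores.
    """
    scores = np.sort(np.asarray(subject_means, dtype=float))
    n = len(scores)
    if n < 4:
        raise DomainError(f"effect-size splits need at least 4 subjects, got {n}")
    pooled_sd = float(np.std(np.asarray(subject_means, dtype=float), ddof=1))

    def row(label: str, g1: np.ndarray, g2: np.ndarray) -> dict:
        if len(g1) < 2 or len(g2) < 2:
            raise DomainError(f"{label}: each group needs at least 2 subjects")
        m1, s1 = _group_stats(g1)
        m2, s2 = _group_stats(g2)
        diff = m2 - m1
        center = (m1 + m2) / 2.0
        return {
            "split": label,
            "mean1": m1,
            "sd1": s1,
            "mean2": m2,
            "sd2": s2,
            "difference": diff,
            "percent_difference": float("nan") if center == 0 else diff / center * 100.0,
            "cohens_d": float("nan") if pooled_sd == 0 else diff / pooled_sd,
        }

    half = n // 2
    quarter = n // 4
    rows = [
        row("median_split", scores[:half], scores[n - half:]),
        row("quartile_split", scores[quarter:half], scores[half : n - quarter]),
    ]
    if scenario_table is not None and contrast is not None:
        missing = [c for c in contrast if c not in scenario_table.columns]
        if missing:
            raise DomainError(f"scenario contrast references unknown scenarios: {missing}")
        g1 = scenario_table[contrast[0]].dropna().to_numpy(dtype=float)
        g2 = scenario_table[contrast[1]].dropna().to_numpy(dtype=float)
        rows.append(row("scenario_contrast", g1, g2))
    return pd.DataFrame(rows).set_index("split")


def instrument_effect_sizes(
    table: pd.DataFrame,
    instrument: str,
    contrast: Tuple[str, str] = ("endobronchial_migration", "symptomatic_bradycardia"),
) -> pd.DataFrame:
    """Convenience wrapper: effect sizes straight from a long rating table."""
    totals = rating_totals(table, instrument)
    rater_avg = totals.groupby(["subject_id", "scenario"])["total"].mean().reset_index()
    subject_means = rater_avg.groupby("subject_id")["total"].mean()
    scenario_table = rater_avg.pivot(index="subject_id", columns="scenario", values="total")
    use = contrast if all(c in scenario_table.columns for c in contrast) else None
    return effect_size_table(subject_means, scenario_table if use else None, use)
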