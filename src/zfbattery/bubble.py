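"""Bubble-plot summarization: merge related measures into categories.

Related behavioral measures (e.g. all bout-magnitude kinematics) are
combined into named categories.  For each category and each effect sign,
the summary records the percent of significant measures in the category
(bubble size) and the mean SSMD over that signed significant subset
(bubble color).  Increased and decreased measures are summarized as
separate bubbles because both can occur within one category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .stats import StatResult

__all__ = [
    "CategorySummary",
    "default_category_map",
    "summarize_categories",
    "summarize_by_epoch",
    "bubble_table_export",
]

SIGNS = ("increased", "decreased")


@dataclass
class CategorySummary:
    """One bubble: a category-and-sign cell of the summary plot."""

    category: str
    sign: str  # "increased" | "decreased"
    percent_significant: float
    mean_ssmd_significant: float
    n_measures: int
    n_significant: int


_BASELINE_CATEGORIES = {
    "bout_count": "bout frequency",
    "mean_center_fraction": "location preference",
    "mean_displacement_px": "bout magnitude",
    "mean_distance_px": "bout magnitude",
    "mean_duration_ms": "bout magnitude",
    "mean_velocity_px_ms": "bout magnitude",
    "mean_revolutions": "bout magnitude",
    "seizure_count": "seizure-like",
}

_STIM_CATEGORIES = {
    "dark_flash": "dark flash response",
    "light_flash": "light flash response",
    "tap_strong": "acoustic response",
    "tap_weak": "acoustic response",
    "prepulse": "acoustic response",
}


def _categorize(measure: str) -> str | None:
    if measure in _BASELINE_CATEGORIES:
        return _BASELINE_CATEGORIES[measure]
    if measure.startswith("habituation_index["):
        return "habituation"
    if "[" in measure and measure.endswith("]"):
        stim_type = measure[measure.index("[") + 1:-1].split(":")[-1]
        return _STIM_CATEGORIES.get(stim_type)
    return None


def default_category_map(results: list[StatResult]) -> dict[str, str]:
    """Category assignment for every measure appearing in ``results``,
    following the battery's standard grouping; raises if a measure cannot
    be categorized."""
    cmap: dict[str, str] = {}
    unknown = []
    for r in results:
        cat = _categorize(r.measure)
        if cat is None:
            unknown.append(r.measure)
        else:
            cmap[r.measure] = cat
    if unknown:
        raise ValidationError(f"no default category for measure(s): {sorted(set(unknown))}")
    return cmap


def summarize_categories(results: list[StatResult],
                         category_map: dict[str, str],
                         alpha: float = 0.05) -> list[CategorySummary]:
    """Aggregate per-measure results into signed category bubbles.

    A result is significant when p < alpha (strict); it contributes to the
    "increased" bubble when its SSMD is > 0 and to "decreased" when < 0
    (a significant result with SSMD exactly 0 contributes to neither).
    Percentages use the category's total measure count as denominator, so
    paired bubbles of one category are comparable.  Category-sign cells
    with no significant results produce no entry.
    """
    unmapped = sorted({r.measure for r in results if r.measure not in category_map})
    if unmapped:
        raise ValidationError(f"unmapped measure(s): {unmapped}")
    by_cat: dict[str, list[StatResult]] = {}
    for r in results:
        by_cat.setdefault(category_map[r.measure], []).append(r)
    out: list[CategorySummary] = []
    for cat in sorted(by_cat):
        group = by_cat[cat]
        total = len(group)
        for sign in SIGNS:
            if sign == "increased":
                sig = [r for r in group if r.p_value < alpha and r.ssmd > 0]
            else:
                sig = [r for r in group if r.p_value < alpha and r.ssmd < 0]
            if not sig:
                continue
            mean_ssmd = sum(r.ssmd for r in sig) / len(sig)
            out.append(CategorySummary(
                category=cat,
                sign=sign,
                percent_significant=100.0 * len(sig) / total,
                mean_ssmd_significant=mean_ssmd,
                n_measures=total,
                n_significant=len(sig),
            ))
    return out


def summarize_by_epoch(results: list[StatResult], category_map: dict[str, str],
                       alpha: float = 0.05) -> dict[str, list[CategorySummary]]:
    """Per-epoch summaries (categories aggregated within each epoch)."""
    by_epoch: dict[str, list[StatResult]] = {}
    for r in results:
        by_epoch.setdefault(r.epoch, []).append(r)
    return {epoch: summarize_categories(rs, category_map, alpha)
            for epoch, rs in sorted(by_epoch.items())}


def bubble_table_export(summaries) -> pd.DataFrame:
    """Long-format table for plotting: one row per (category, epoch,
    sign) with bubble size = percent significant and color value = mean
    SSMD.  Accepts a plain summary list (epoch ``all``) or a mapping
    epoch -> summaries."""
    if isinstance(summaries, list):
        summaries = {"all": summaries}
    rows = []
    for epoch in sorted(summaries):
        for s in summaries[epoch]:
            rows.append({
                "category": s.category,
                "epoch": epoch,
                "sign": s.sign,
                "percent_significant": s.percent_significant,
                "mean_ssmd_significant": s.mean_ssmd_significant,
                "n_measures": s.n_measures,
                "n_significant": s.n_significant,
            })
    cols = ["category", "epoch", "sign", "percent_significant",
            "mean_ssmd_significant", "n_measures", "n_significant"]
    return pd.DataFrame(rows, columns=cols)
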