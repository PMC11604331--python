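"""Snapshot summaries and between-year comparison statistics.

All statistics are descriptive (the underlying monitoring design calls for
no inferential tests).  Conventions, stated once: the median of an even-
sized group is the midpoint of the two central order statistics; P25/P75
use linear interpolation; class percentages are kept at full precision
internally and rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

CLASSES = ("A", "B", "C", "D", "E")

#: Composition columns summarised in the per-group tables.
NUTRIENT_COLUMNS = (
    "energy_kj", "sugars_g", "sfa_g", "salt_g", "protein_g", "fibre_g",
)

ChangeMetric = Literal["total_variation", "abs_sum"]


@dataclass
class SnapshotSummary:
    """Per-group descriptive statistics of one scored snapshot year."""

    year: int
    n: pd.Series                       # group -> product count
    nutrient_summary: pd.DataFrame     # group x (nutrient, median|p25|p75)
    class_distribution: pd.DataFrame   # group x A..E, percentages
    mean_final_sum: pd.Series          # group -> mean of the final sum
    histograms: Mapping[str, pd.Series] = field(default_factory=dict)


def _class_percentages(classes: pd.Series) -> pd.Series:
    counts = classes.value_counts().reindex(CLASSES, fill_value=0)
    return 100.0 * counts / counts.sum()


def summarize_snapshot(scored: pd.DataFrame, year: int) -> SnapshotSummary:
    """Summarise one year of the per-product score table.

    Produces the group-level median/IQR nutrient table, the class
    distribution in percent, the mean final sum, and integer-binned
    final-sum histograms.
    """
    df = scored[scored["year"] == year]
    if df.empty:
        raise ValueError(f"no scored records for year {year}")
    groups = sorted(df["food_group"].unique())

    n = df.groupby("food_group").size().reindex(groups)

    stats = {}
    for nutrient in NUTRIENT_COLUMNS:
        grouped = df.groupby("food_group")[nutrient]
        stats[(nutrient, "median")] = grouped.median()
        stats[(nutrient, "p25")] = grouped.quantile(0.25)
        stats[(nutrient, "p75")] = grouped.quantile(0.75)
    nutrient_summary = pd.DataFrame(stats).reindex(groups)
    nutrient_summary.columns = pd.MultiIndex.from_tuples(
        nutrient_summary.columns, names=["nutrient", "stat"]
    )

    class_distribution = (
        df.groupby("food_group")["nutri_class"]
        .apply(_class_percentages)
        .unstack()
        .reindex(groups)[list(CLASSES)]
    )

    mean_final_sum = df.groupby("food_group")["final_sum"].mean().reindex(groups)

    histograms = {
        group: score_histogram(scored, group, year) for group in groups
    }
    return SnapshotSummary(
        year=year,
        n=n,
        nutrient_summary=nutrient_summary,
        class_distribution=class_distribution,
        mean_final_sum=mean_final_sum,
        histograms=histograms,
    )


def pp_change(summary1: SnapshotSummary, summary2: SnapshotSummary) -> pd.DataFrame:
    """Percentage-point change per class, later year minus earlier year.

    Restricted to the food groups present in both years (a change is
    undefined for a group observed once).  Rows sum to zero up to rounding.
    """
    common = summary1.class_distribution.index.intersection(
        summary2.class_distribution.index
    )
    delta = (
        summary2.class_distribution.loc[common]
        - summary1.class_distribution.loc[common]
    )
    return delta


def overall_change(
    delta: pd.Series | pd.DataFrame, metric: ChangeMetric = "total_variation"
) -> pd.Series | float:
    """Scalar size of a per-class percentage-point change.

    ``total_variation`` (default) is half the sum of absolute changes — the
    percentage of products that moved class; ``abs_sum`` is the raw sum of
    absolute per-class changes.
    """
    if metric not in ("total_variation", "abs_sum"):
        raise ValueError(f"unknown change metric {metric!r}")
    if isinstance(delta, pd.DataFrame):
        total = delta.abs().sum(axis=1)
    else:
        total = delta.abs().sum()
    return total / 2 if metric == "total_variation" else total


def top_k(
    delta: pd.DataFrame, k: int = 5, metric: ChangeMetric = "total_variation"
) -> list[str]:
    """The ``k`` groups with the largest overall class-distribution change.

    Ties are broken by group-key order, so the selection is deterministic.
    """
    scores = overall_change(delta, metric)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [group for group, _ in ranked[:k]]


@dataclass
class MatchedEanReport:
    """Sensitivity analysis over products sold in both years (same EAN)."""

    n_matched: int
    per_group: pd.DataFrame            # group x (n_matched, n_changed, pct_changed)
    class_distribution_year1: pd.DataFrame
    class_distribution_year2: pd.DataFrame


def matched_ean_sensitivity(
    scored1: pd.DataFrame, scored2: pd.DataFrame
) -> MatchedEanReport:
    """Compare class letters of identical products present in both years.

    Inner-joins the two scored tables on EAN; a product counts as changed
    when its class letter differs between years (a final-sum change within
    one class is no change).  Grouping follows the earlier year's food
    group.  Duplicate EANs within a year are an error.
    """
    for label, df in (("year 1", scored1), ("year 2", scored2)):
        dupes = df.loc[df["ean"].duplicated(), "ean"].unique()
        if len(dupes):
            raise ValueError(
                f"duplicate EANs in {label} snapshot: {sorted(dupes)[:10]}"
            )
    merged = scored1.merge(
        scored2, on="ean", suffixes=("_y1", "_y2"), how="inner"
    )
    empty_dist = pd.DataFrame(columns=list(CLASSES))
    if merged.empty:
        per_group = pd.DataFrame(columns=["n_matched", "n_changed", "pct_changed"])
        return MatchedEanReport(0, per_group, empty_dist, empty_dist)

    merged["changed"] = merged["nutri_class_y1"] != merged["nutri_class_y2"]
    grouped = merged.groupby("food_group_y1")
    per_group = pd.DataFrame(
        {
            "n_matched": grouped.size(),
            "n_changed": grouped["changed"].sum().astype(int),
        }
    )
    per_group["pct_changed"] = 100.0 * per_group["n_changed"] / per_group["n_matched"]
    per_group.index.name = "food_group"

    dist1 = (
        merged.groupby("food_group_y1")["nutri_class_y1"]
        .apply(_class_percentages)
        .unstack()[list(CLASSES)]
    )
    dist2 = (
        merged.groupby("food_group_y1")["nutri_class_y2"]
        .apply(_class_percentages)
        .unstack()[list(CLASSES)]
    )
    return MatchedEanReport(len(merged), per_group, dist1, dist2)


def median_by_class(
    scored: pd.DataFrame, nutrient: str, group: str
) -> pd.DataFrame:
    """Median of ``nutrient`` per class letter and year within one group.

    Classes with no products in a year are absent (NaN), never reported as
    zero.  Rows: class letters observed in at least one year; columns:
    a (year, stat) MultiIndex with the median and the class size.
    """
    df = scored[scored["food_group"] == group]
    if df.empty:
        raise ValueError(f"no scored records for group {group!r}")
    pieces = {}
    for year, ydf in df.groupby("year"):
        med = ydf.groupby("nutri_class")[nutrient].median()
        n = ydf.groupby("nutri_class").size()
        pieces[(year, "median")] = med
        pieces[(year, "n")] = n
    out = pd.DataFrame(pieces)
    out = out.reindex([c for c in CLASSES if c in out.index])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["year", "stat"])
    out.index.name = "nutri_class"
    return out


def score_histogram(scored: pd.DataFrame, group: str, year: int) -> pd.Series:
    """Integer-binned frequency of the final sum for one group-year."""
    df = scored[(scored["food_group"] == group) & (scored["year"] == year)]
    if df.empty:
        raise ValueError(f"no scored records for group {group!r} in {year}")
    sums = df["final_sum"].astype(int)
    bins = np.arange(sums.min(), sums.max() + 1)
    counts = sums.value_counts().reindex(bins, fill_value=0).sort_index()
    counts.name = "count"
    counts.index.name = "final_sum"
    return counts


def relative_median_change(
    summary1: SnapshotSummary,
    summary2: SnapshotSummary,
    nutrients: Iterable[str] = ("sugars_g", "sfa_g", "salt_g", "energy_kj"),
) -> pd.DataFrame:
    """Relative change (%) of per-group median nutrient contents.

    Used to pick, per food group, the nutrient whose median changed the
    most between the two snapshot years; zero medians in the earlier year
    yield NaN rather than an infinite ratio.
    """
    common = summary1.nutrient_summary.index.intersection(
        summary2.nutrient_summary.index
    )
    out = {}
    for nutrient in nutrients:
        m1 = summary1.nutrient_summary.loc[common, (nutrient, "median")]
        m2 = summary2.nutrient_summary.loc[common, (nutrient, "median")]
        out[nutrient] = 100.0 * (m2 - m1) / m1.replace(0, np.nan)
    return pd.DataFrame(out)
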