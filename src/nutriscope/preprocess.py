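"""Data-preparation rules applied before scoring.

Fixed pipeline order (logged): keep processed foods -> drop records missing
a mandatory scoring component (energy, salt, SFA, sugars, protein) -> impute
missing fibre with the group-year mean of the observed values -> assign the
per-group fruit/vegetable/legume estimate where none is declared -> drop
group-years smaller than the minimum size.  Fibre and FVL missingness never
excludes a record; the two are filled, not filtered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .records import FoodGroupTaxonomy, FoodRecord

logger = logging.getLogger(__name__)

#: Components whose absence excludes a record from the analysis.
MANDATORY_COMPONENTS = ("energy_kj", "salt_g", "sfa_g", "sugars_g", "protein_g")

GroupYear = tuple[str, int]


@dataclass
class PreprocessReport:
    """Accounting of every preparation step.

    Satisfies ``input_count == retained_count + total excluded`` and
    ``fibre_imputed[g, y]`` equals the number of retained records in that
    group-year that arrived without a declared fibre content.
    """

    input_count: int = 0
    retained_count: int = 0
    excluded_not_processed: int = 0
    excluded_missing_mandatory: dict[GroupYear, int] = field(default_factory=dict)
    excluded_small_group: dict[GroupYear, int] = field(default_factory=dict)
    fibre_imputed: dict[GroupYear, int] = field(default_factory=dict)
    imputation_means: dict[GroupYear, float] = field(default_factory=dict)

    @property
    def excluded_count(self) -> int:
        return (
            self.excluded_not_processed
            + sum(self.excluded_missing_mandatory.values())
            + sum(self.excluded_small_group.values())
        )

    def reconciles(self) -> bool:
        return self.input_count == self.retained_count + self.excluded_count


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def filter_processed(records: Iterable[FoodRecord]) -> list[FoodRecord]:
    """Keep processed foods only."""
    return [r for r in records if r.is_processed]


def filter_missing_mandatory(
    records: Iterable[FoodRecord],
) -> tuple[list[FoodRecord], dict[GroupYear, int]]:
    """Drop records missing any mandatory component; count drops per group-year."""
    kept: list[FoodRecord] = []
    excluded: dict[GroupYear, int] = {}
    for r in records:
        if any(_is_missing(getattr(r, c)) for c in MANDATORY_COMPONENTS):
            key = (r.food_group, r.year)
            excluded[key] = excluded.get(key, 0) + 1
        else:
            kept.append(r)
    return kept, excluded


def impute_fibre(
    records: Iterable[FoodRecord],
) -> tuple[list[FoodRecord], dict[GroupYear, float], dict[GroupYear, int]]:
    """Fill missing fibre with the group-year mean of observed fibre.

    Observed values are left bit-identical.  A group-year with missing fibre
    but no observed value to average is an error (the rule is undefined
    there and silently writing zeros would bias the fibre points).
    """
    records = list(records)
    sums: dict[GroupYear, float] = {}
    counts: dict[GroupYear, int] = {}
    missing: dict[GroupYear, int] = {}
    for r in records:
        key = (r.food_group, r.year)
        if _is_missing(r.fibre_g):
            missing[key] = missing.get(key, 0) + 1
        else:
            sums[key] = sums.get(key, 0.0) + r.fibre_g
            counts[key] = counts.get(key, 0) + 1

    means: dict[GroupYear, float] = {}
    for key, n_missing in missing.items():
        if key not in counts:
            raise ValueError(
                f"cannot impute fibre for group {key[0]!r} in {key[1]}: "
                "no observed fibre values"
            )
        means[key] = sums[key] / counts[key]

    out = [
        r.model_copy(update={"fibre_g": means[(r.food_group, r.year)]})
        if _is_missing(r.fibre_g)
        else r
        for r in records
    ]
    return out, means, missing


def assign_fvl(
    records: Iterable[FoodRecord], taxonomy: FoodGroupTaxonomy
) -> list[FoodRecord]:
    """Give records without a declared FVL share their group's estimate."""
    return [
        r.model_copy(update={"fvl_pct": taxonomy.fvl_estimate_for(r.food_group)})
        if _is_missing(r.fvl_pct)
        else r
        for r in records
    ]


def filter_small_groups(
    records: Iterable[FoodRecord], min_size: int = 10
) -> tuple[list[FoodRecord], dict[GroupYear, int]]:
    """Drop whole group-years with fewer than ``min_size`` records."""
    records = list(records)
    sizes: dict[GroupYear, int] = {}
    for r in records:
        key = (r.food_group, r.year)
        sizes[key] = sizes.get(key, 0) + 1
    dropped = {key: n for key, n in sizes.items() if n < min_size}
    kept = [r for r in records if (r.food_group, r.year) not in dropped]
    return kept, dropped


def preprocess(
    records: Iterable[FoodRecord],
    taxonomy: FoodGroupTaxonomy,
    min_group_size: int = 10,
) -> tuple[list[FoodRecord], PreprocessReport]:
    """Run the full preparation pipeline in its fixed order."""
    records = list(records)
    report = PreprocessReport(input_count=len(records))

    step = filter_processed(records)
    report.excluded_not_processed = len(records) - len(step)
    logger.info("processed-food filter: %d -> %d", len(records), len(step))

    step, report.excluded_missing_mandatory = filter_missing_mandatory(step)
    logger.info("mandatory-component filter: kept %d", len(step))

    step, report.imputation_means, report.fibre_imputed = impute_fibre(step)
    logger.info("fibre imputation: %d values filled", sum(report.fibre_imputed.values()))

    step = assign_fvl(step, taxonomy)

    step, report.excluded_small_group = filter_small_groups(step, min_group_size)
    logger.info("small-group filter: kept %d", len(step))

    report.retained_count = len(step)
    return step, report
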