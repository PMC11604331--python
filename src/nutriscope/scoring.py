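"""Point allocation and classification under a Nutri-Score scheme.

The final sum of points is the negative (unfavourable) sum N — energy,
sugars, saturated fat (or the SFA/total-fat ratio for fats, oils, nuts and
seeds), salt, plus the sweetener penalty for beverages — minus the applied
positive sum P (protein where counted, fibre, fruits/vegetables/legumes).
Lower sums map to better classes.  Mineral waters are classified A outright;
all other beverages can reach B at best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .records import FoodGroupTaxonomy, FoodRecord, fold_text
from .scheme import BoundaryConvention, CategoryScheme, PointGrid, ScoringScheme


def component_points(
    value: float, grid: PointGrid, convention: BoundaryConvention = "strict"
) -> int:
    """Points earned by ``value`` on ``grid``.

    Under the default ``strict`` convention a value earns the points of the
    highest cutoff it strictly exceeds; under ``inclusive`` a value sitting
    exactly on a cutoff already earns that cutoff's points.
    """
    if value < 0:
        raise ValueError(f"{grid.component}: negative quantity {value}")
    if convention not in ("strict", "inclusive"):
        raise ValueError(f"unknown boundary convention {convention!r}")
    crossed = 0
    for i, cutoff in enumerate(grid.cutoffs):
        if value > cutoff or (convention == "inclusive" and value == cutoff):
            crossed = i + 1
        else:
            break
    return 0 if crossed == 0 else grid.points[crossed - 1]


def detect_red_meat(name: str, ingredients: str, keywords: Iterable[str]) -> bool:
    """Case-insensitive, diacritics-folded keyword search over label texts."""
    return _match_keywords(name, ingredients, keywords)


def detect_sweeteners(name: str, ingredients: str, keywords: Iterable[str]) -> bool:
    """Flag non-nutritive sweeteners from name/ingredient text."""
    return _match_keywords(name, ingredients, keywords)


def _match_keywords(name: str, ingredients: str, keywords: Iterable[str]) -> bool:
    haystack = fold_text(f"{name} {ingredients}")
    return any(fold_text(kw) in haystack for kw in keywords if kw)


@dataclass(frozen=True)
class ScoreFlags:
    """Per-product special-rule switches (auto-detected when not supplied)."""

    is_red_meat: bool = False
    is_cheese: bool = False
    has_sweeteners: bool = False


@dataclass(frozen=True)
class ScoreResult:
    """Component points and classification for one product."""

    ean: str
    category: str
    points: Mapping[str, int]
    negative_sum: int
    positive_sum: int          # applied positive points (protein only if counted)
    protein_counted: bool
    final_sum: int
    nutri_class: str
    flags: ScoreFlags = field(default_factory=ScoreFlags)


def classify(final_sum: int, category: str, scheme: ScoringScheme) -> str:
    """Letter A–E for an integer final sum; monotone in the sum."""
    if final_sum != int(final_sum):
        raise ValueError(f"final sum must be an integer, got {final_sum}")
    final_sum = int(final_sum)
    cat = scheme.category(category)
    for letter, (lo, hi) in cat.class_bounds.items():
        if (lo is None or final_sum >= lo) and (hi is None or final_sum <= hi):
            return letter
    raise ValueError(f"final sum {final_sum} not covered by {category} class bounds")


def negative_points(
    record: FoodRecord,
    scheme: ScoringScheme,
    category: str,
    flags: ScoreFlags = ScoreFlags(),
    convention: BoundaryConvention = "strict",
) -> tuple[int, dict[str, int]]:
    """Unfavourable points N with the per-component breakdown."""
    cat = scheme.category(category)
    pts: dict[str, int] = {}
    pts["energy"] = component_points(record.energy_kj, cat.grids["energy"], convention)
    pts["sugars"] = component_points(record.sugars_g, cat.grids["sugars"], convention)
    if "sfa_fat_ratio" in cat.grids:
        if record.total_fat_g is None:
            raise ValueError(
                f"{record.ean}: total fat is required to score the "
                f"{category} category (SFA/total-fat ratio)"
            )
        ratio = 0.0 if record.total_fat_g == 0 else 100.0 * record.sfa_g / record.total_fat_g
        pts["sfa_fat_ratio"] = component_points(ratio, cat.grids["sfa_fat_ratio"], convention)
    else:
        pts["sfa"] = component_points(record.sfa_g, cat.grids["sfa"], convention)
    pts["salt"] = component_points(record.salt_g, cat.grids["salt"], convention)
    if category == "beverage" and flags.has_sweeteners:
        pts["sweeteners"] = scheme.rules.sweetener_points
    return sum(pts.values()), pts


def positive_points(
    record: FoodRecord,
    negative_sum: int,
    scheme: ScoringScheme,
    category: str,
    flags: ScoreFlags = ScoreFlags(),
    convention: BoundaryConvention = "strict",
) -> tuple[int, bool, dict[str, int]]:
    """Applied favourable points P and whether protein was counted.

    Requires fibre and the fruit/vegetable/legume share to be present
    (imputed/estimated upstream).  Protein is dropped for products whose
    negative sum reaches the category threshold, unless the product earns
    maximal FVL points or is a cheese; red-meat protein is capped.
    """
    cat = scheme.category(category)
    if record.fibre_g is None:
        raise ValueError(f"{record.ean}: fibre must be imputed before scoring")
    if record.fvl_pct is None:
        raise ValueError(f"{record.ean}: fvl_pct must be estimated before scoring")

    protein = component_points(record.protein_g, cat.grids["protein"], convention)
    if flags.is_red_meat:
        protein = min(protein, scheme.rules.red_meat_protein_cap)
    fibre = component_points(record.fibre_g, cat.grids["fibre"], convention)
    fvl = component_points(record.fvl_pct, cat.grids["fvl"], convention)

    counted = True
    if cat.protein_exclusion_threshold is not None and negative_sum >= cat.protein_exclusion_threshold:
        exempt_fvl = (
            cat.fvl_exemption_points is not None and fvl >= cat.fvl_exemption_points
        )
        exempt_cheese = flags.is_cheese and scheme.rules.cheese_protein_always_counted
        counted = exempt_fvl or exempt_cheese

    pts = {"protein": protein, "fibre": fibre, "fvl": fvl}
    applied = fibre + fvl + (protein if counted else 0)
    return applied, counted, pts


def derive_flags(record: FoodRecord, scheme: ScoringScheme) -> ScoreFlags:
    """Default special-rule flags from the label texts and food group."""
    return ScoreFlags(
        is_red_meat=detect_red_meat(record.name, record.ingredients, scheme.red_meat_keywords),
        is_cheese=record.food_group == "cheeses",
        has_sweeteners=detect_sweeteners(
            record.name, record.ingredients, scheme.sweetener_keywords
        ),
    )


def score_record(
    record: FoodRecord,
    scheme: ScoringScheme,
    taxonomy: FoodGroupTaxonomy,
    flags: Optional[ScoreFlags] = None,
    convention: BoundaryConvention = "strict",
) -> ScoreResult:
    """Deterministic score and class for one preprocessed record."""
    category = taxonomy.category_for(record.food_group)
    if flags is None:
        flags = derive_flags(record, scheme)

    n_sum, neg_pts = negative_points(record, scheme, category, flags, convention)
    p_sum, counted, pos_pts = positive_points(
        record, n_sum, scheme, category, flags, convention
    )
    final = n_sum - p_sum
    if category == "beverage" and record.is_water:
        letter = scheme.rules.water_class
    else:
        letter = classify(final, category, scheme)
    return ScoreResult(
        ean=record.ean,
        category=category,
        points={**neg_pts, **pos_pts},
        negative_sum=n_sum,
        positive_sum=p_sum,
        protein_counted=counted,
        final_sum=final,
        nutri_class=letter,
        flags=flags,
    )


#: Columns of the per-product score table.
SCORE_COLUMNS = [
    "ean", "name", "food_group", "category", "year",
    "energy_kj", "sugars_g", "sfa_g", "salt_g", "protein_g", "fibre_g", "fvl_pct",
    "negative_sum", "positive_sum", "protein_counted", "final_sum", "nutri_class",
    "is_water",
]


def score_table(
    records: Iterable[FoodRecord],
    scheme: ScoringScheme,
    taxonomy: FoodGroupTaxonomy,
    convention: BoundaryConvention = "strict",
) -> pd.DataFrame:
    """Score every record into a tidy per-product table.

    The table carries the composition columns alongside the scores so the
    downstream summaries (medians by class, histograms) need no joins.
    """
    rows = []
    for rec in records:
        res = score_record(rec, scheme, taxonomy, convention=convention)
        rows.append(
            {
                "ean": rec.ean,
                "name": rec.name,
                "food_group": rec.food_group,
                "category": res.category,
                "year": rec.year,
                "energy_kj": rec.energy_kj,
                "sugars_g": rec.sugars_g,
                "sfa_g": rec.sfa_g,
                "salt_g": rec.salt_g,
                "protein_g": rec.protein_g,
                "fibre_g": rec.fibre_g,
                "fvl_pct": rec.fvl_pct,
                "negative_sum": res.negative_sum,
                "positive_sum": res.positive_sum,
                "protein_counted": res.protein_counted,
                "final_sum": res.final_sum,
                "nutri_class": res.nutri_class,
                "is_water": rec.is_water,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
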