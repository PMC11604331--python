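"""Branded-food data model, food-group taxonomy, and snapshot I/O.

A *snapshot* is one year's view of a branded-food market: one row per
product with its EAN barcode, label texts, food-group key and per-100 g
(per-100 mL for beverages) composition.  Snapshots are stored as plain CSV
with a fixed, documented column order; missing values (undeclared fibre,
undeclared fruit/vegetable/legume share, total fat) are empty cells, never
zero — zero is a legal nutrient value.
"""

from __future__ import annotations

import logging
import math
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

try:  # py>=3.9
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

logger = logging.getLogger(__name__)

#: Scoring categories recognised by the engine.
CATEGORIES = ("general_solid", "beverage", "fats_oils_nuts_seeds")

#: Canonical snapshot column order (CSV header).
SNAPSHOT_COLUMNS = [
    "ean",
    "name",
    "ingredients",
    "food_group",
    "year",
    "energy_kj",
    "sugars_g",
    "sfa_g",
    "salt_g",
    "protein_g",
    "fibre_g",
    "fvl_pct",
    "total_fat_g",
    "is_water",
    "is_processed",
]

#: Salt (g) per gram of sodium, used when a source declares sodium instead.
SODIUM_TO_SALT = 2.5


class FoodRecord(BaseModel):
    """One branded product's label data and composition for one year.

    Quantities are per 100 g for solid foods and per 100 mL for beverages;
    the taxonomy's scoring category decides the interpretation.  ``fibre_g``,
    ``fvl_pct`` and ``total_fat_g`` may be missing (``None``); missingness is
    meaningful and preserved through I/O.
    """

    model_config = ConfigDict(frozen=True)

    ean: str
    name: str = ""
    ingredients: str = ""
    food_group: str
    year: int
    energy_kj: float
    sugars_g: float
    sfa_g: float
    salt_g: float
    protein_g: float
    fibre_g: Optional[float] = None
    fvl_pct: Optional[float] = None
    total_fat_g: Optional[float] = None
    is_water: bool = False
    is_processed: bool = True

    @field_validator(
        "energy_kj", "sugars_g", "sfa_g", "salt_g", "protein_g",
        "fibre_g", "total_fat_g",
    )
    @classmethod
    def _non_negative(cls, v, info):
        if v is not None and v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("sugars_g")
    @classmethod
    def _sugars_bounded(cls, v):
        if v is not None and v > 100:
            raise ValueError(f"sugars_g cannot exceed 100 g/100 g, got {v}")
        return v

    @field_validator("fvl_pct")
    @classmethod
    def _fvl_bounded(cls, v):
        if v is not None and not (0 <= v <= 100):
            raise ValueError(f"fvl_pct must lie in [0, 100], got {v}")
        return v

    @model_validator(mode="after")
    def _sfa_within_fat(self):
        if self.total_fat_g is not None and self.sfa_g > self.total_fat_g + 1e-9:
            raise ValueError(
                f"sfa_g ({self.sfa_g}) exceeds total_fat_g ({self.total_fat_g})"
            )
        return self


@dataclass(frozen=True)
class FoodGroup:
    key: str
    name: str
    category: str
    fvl_estimate: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown scoring category {self.category!r} for group {self.key!r}"
            )


@dataclass(frozen=True)
class FoodGroupTaxonomy:
    """Ordered food-group list with scoring-category map and FVL defaults."""

    groups: tuple[FoodGroup, ...]
    _by_key: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        by_key = {g.key: g for g in self.groups}
        if len(by_key) != len(self.groups):
            raise ValueError("duplicate food-group keys in taxonomy")
        object.__setattr__(self, "_by_key", by_key)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def keys(self) -> list[str]:
        return [g.key for g in self.groups]

    def group(self, key: str) -> FoodGroup:
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"unknown food group {key!r}") from None

    def category_for(self, key: str) -> str:
        return self.group(key).category

    def fvl_estimate_for(self, key: str) -> float:
        return self.group(key).fvl_estimate

    def display_name(self, key: str) -> str:
        return self.group(key).name

    @classmethod
    def from_dict(cls, payload: dict) -> "FoodGroupTaxonomy":
        groups = tuple(
            FoodGroup(
                key=g["key"],
                name=g.get("name", g["key"]),
                category=g["category"],
                fvl_estimate=float(g.get("fvl_estimate", 0.0)),
            )
            for g in payload["groups"]
        )
        return cls(groups)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FoodGroupTaxonomy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FoodGroupTaxonomy":
        """The packaged 21-group taxonomy (Dutch-market structure)."""
        text = (_resource_files("nutriscope") / "data" / "taxonomy_nl.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


class SnapshotValidationError(ValueError):
    """Raised when snapshot rows violate the record invariants.

    ``errors`` is a list of ``(row_index, message)`` pairs.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        preview = "; ".join(f"row {i}: {msg}" for i, msg in self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} invalid snapshot row(s): {preview}{more}")


def _clean_optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not math.isnan(float(value)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no", "", "nan"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def frame_to_records(
    df: pd.DataFrame, taxonomy: FoodGroupTaxonomy, year: int | None = None
) -> list[FoodRecord]:
    """Validate a snapshot table into :class:`FoodRecord` objects.

    Rows that violate the record invariants or reference unknown food groups
    are collected and reported together in a :class:`SnapshotValidationError`
    with their row indices.  ``year`` filters a multi-year table.
    """
    if "salt_g" not in df.columns and "sodium_g" in df.columns:
        df = df.copy()
        df["salt_g"] = df["sodium_g"].astype(float) * SODIUM_TO_SALT
        logger.info("converted sodium_g to salt_g at %.1f g salt per g sodium", SODIUM_TO_SALT)

    missing_cols = [c for c in SNAPSHOT_COLUMNS if c not in df.columns and c not in
                    ("is_water", "is_processed", "fibre_g", "fvl_pct", "total_fat_g",
                     "name", "ingredients")]
    if missing_cols:
        raise ValueError(f"snapshot is missing required columns: {missing_cols}")

    if year is not None:
        df = df[df["year"].astype(int) == int(year)]

    records: list[FoodRecord] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        group = str(row["food_group"])
        if group not in taxonomy:
            errors.append((idx, f"unknown food group {group!r}"))
            continue
        try:
            records.append(
                FoodRecord(
                    ean=str(row["ean"]),
                    name="" if pd.isna(row.get("name")) else str(row.get("name", "")),
                    ingredients=""
                    if pd.isna(row.get("ingredients"))
                    else str(row.get("ingredients", "")),
                    food_group=group,
                    year=int(row["year"]),
                    energy_kj=float(row["energy_kj"]),
                    sugars_g=float(row["sugars_g"]),
                    sfa_g=float(row["sfa_g"]),
                    salt_g=float(row["salt_g"]),
                    protein_g=float(row["protein_g"]),
                    fibre_g=_clean_optional(row.get("fibre_g")),
                    fvl_pct=_clean_optional(row.get("fvl_pct")),
                    total_fat_g=_clean_optional(row.get("total_fat_g")),
                    is_water=_parse_bool(row.get("is_water", False)),
                    is_processed=_parse_bool(row.get("is_processed", True)),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append((idx, _summarize_error(exc)))
    if errors:
        raise SnapshotValidationError(errors)
    return records


def _summarize_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        return str(first.get("msg", exc))
    return str(exc)


def records_to_frame(records: Iterable[FoodRecord]) -> pd.DataFrame:
    """Snapshot table (canonical column order) from records."""
    rows = [r.model_dump() for r in records]
    df = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    return df


def read_snapshot(
    path: str | Path, taxonomy: FoodGroupTaxonomy, year: int | None = None
) -> list[FoodRecord]:
    """Read and validate a snapshot CSV.

    The file may hold a single year or several (a ``year`` column is always
    present); pass ``year`` to select one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"ean": str, "name": str, "ingredients": str},
        float_precision="round_trip",
    )
    return frame_to_records(df, taxonomy, year=year)


def write_snapshot(records: Iterable[FoodRecord], path: str | Path) -> Path:
    """Write records to CSV with the canonical header and empty-cell sentinels."""
    path = Path(path)
    df = records_to_frame(records)
    # shortest exact representation, so floats round-trip bit-for-bit
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def fold_text(text: str) -> str:
    """Lower-case and strip diacritics, for keyword matching."""
    decomposed = unicodedata.normalize("NFKD", text.lower())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))
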