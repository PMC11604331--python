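"""The Nutri-Score scoring scheme as data.

The engine is deliberately data-driven: every point grid (cutoffs and the
points earned above each cutoff), every class boundary and every special
rule lives in a YAML document, so the scheme can be audited against the
official algorithm tables and swapped without touching code.  The packaged
default is the updated scheme (solid foods 2022, beverages 2023).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional

import yaml

try:
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    from importlib_resources import files as _resource_files

#: Boundary convention: does a value sitting exactly on a cutoff earn the
#: cutoff's points?  "strict" (official reading, value must exceed the
#: cutoff) or "inclusive" (value >= cutoff earns the points).
BoundaryConvention = Literal["strict", "inclusive"]

COMPONENTS = ("energy", "sugars", "sfa", "sfa_fat_ratio", "salt", "protein", "fibre", "fvl")


@dataclass(frozen=True)
class PointGrid:
    """Step-function mapping a nutrient quantity to integer points.

    ``points[i]`` is earned once the value passes ``cutoffs[i]``; dense grids
    use 1..k, sparse grids (the fruit/vegetable/legume component) skip levels.
    """

    component: str
    cutoffs: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if not self.cutoffs:
            raise ValueError("grid needs at least one cutoff")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError(f"{self.component}: cutoffs must be strictly ascending")
        if len(self.points) != len(self.cutoffs):
            raise ValueError(f"{self.component}: need one points level per cutoff")
        if any(q <= p for p, q in zip((0,) + self.points, self.points)):
            raise ValueError(f"{self.component}: points must be strictly ascending from 0")

    @property
    def max_points(self) -> int:
        return self.points[-1]


@dataclass(frozen=True)
class CategoryScheme:
    """Grids, protein-counting condition and class bounds for one category."""

    category: str
    grids: Mapping[str, PointGrid]
    #: protein points are dropped when the negative sum reaches this value
    #: (None: protein always counted, as for beverages)
    protein_exclusion_threshold: Optional[int]
    #: ...unless the FVL component already earns this many points
    fvl_exemption_points: Optional[int]
    #: letter -> (lo, hi) closed integer interval on the final sum; None = open
    class_bounds: Mapping[str, tuple[Optional[int], Optional[int]]]

    def __post_init__(self):
        self._check_class_bounds()

    def _check_class_bounds(self):
        intervals = sorted(
            self.class_bounds.items(),
            key=lambda kv: -10_000 if kv[1][0] is None else kv[1][0],
        )
        letters = [letter for letter, _ in intervals]
        if letters != sorted(letters):
            raise ValueError(f"{self.category}: class letters out of order: {letters}")
        for (la, (_, hi)), (lb, (lo, _)) in zip(intervals, intervals[1:]):
            if hi is None or lo is None or lo != hi + 1:
                raise ValueError(
                    f"{self.category}: classes {la} and {lb} are not contiguous"
                )
        if intervals[0][1][0] is not None or intervals[-1][1][1] is not None:
            raise ValueError(f"{self.category}: class bounds must cover all sums")


@dataclass(frozen=True)
class SpecialRules:
    red_meat_protein_cap: int = 2
    cheese_protein_always_counted: bool = True
    sweetener_points: int = 4
    water_class: str = "A"


@dataclass(frozen=True)
class ScoringScheme:
    """A complete Nutri-Score scheme: per-category grids, bounds and rules."""

    name: str
    categories: Mapping[str, CategoryScheme]
    rules: SpecialRules
    red_meat_keywords: tuple[str, ...]
    sweetener_keywords: tuple[str, ...]

    def category(self, key: str) -> CategoryScheme:
        try:
            return self.categories[key]
        except KeyError:
            raise KeyError(f"scheme has no category {key!r}") from None

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoringScheme":
        categories = {}
        for cat_key, cat in payload["categories"].items():
            grids = {}
            for comp, spec in cat["grids"].items():
                cutoffs = tuple(float(c) for c in spec["cutoffs"])
                if "points" in spec:
                    points = tuple(int(p) for p in spec["points"])
                else:
                    points = tuple(range(1, len(cutoffs) + 1))
                grids[comp] = PointGrid(component=comp, cutoffs=cutoffs, points=points)
            bounds = {
                letter: (
                    None if lo is None else int(lo),
                    None if hi is None else int(hi),
                )
                for letter, (lo, hi) in cat["class_bounds"].items()
            }
            categories[cat_key] = CategoryScheme(
                category=cat_key,
                grids=grids,
                protein_exclusion_threshold=cat.get("protein_exclusion_threshold"),
                fvl_exemption_points=cat.get("fvl_exemption_points"),
                class_bounds=bounds,
            )
        rules_payload = payload.get("special_rules", {})
        rules = SpecialRules(
            red_meat_protein_cap=int(rules_payload.get("red_meat_protein_cap", 2)),
            cheese_protein_always_counted=bool(
                rules_payload.get("cheese_protein_always_counted", True)
            ),
            sweetener_points=int(rules_payload.get("sweetener_points", 4)),
            water_class=str(rules_payload.get("water_class", "A")),
        )
        keywords = payload.get("keywords", {})
        return cls(
            name=str(payload.get("name", "unnamed-scheme")),
            categories=categories,
            rules=rules,
            red_meat_keywords=tuple(keywords.get("red_meat", ())),
            sweetener_keywords=tuple(keywords.get("sweeteners", ())),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoringScheme":
        """The packaged updated scheme (2022 solid foods / 2023 beverages)."""
        text = (_resource_files("nutriscope") / "data" / "scheme_2023.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))
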