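"""Synthetic branded-food market snapshots.

Emulates the statistical structure of two label-data snapshots of a retail
food supply: per-group right-skewed nutrient distributions (log-normal,
parameterised directly by the target median and IQR), undeclared fibre and
fruit/vegetable/legume shares, products carried over between years by EAN,
reformulation shifts applied to a subset of carried-over products, and
diversification (new year-2 products drawn from a shifted distribution).
A truth table records every applied shift so pipeline results can be
checked against construction.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .records import FoodGroupTaxonomy, FoodRecord

#: Phi^-1(0.75); the quartiles of lognormal(mu, sigma) sit at
#: median * exp(+-Z75 * sigma).
_Z75 = 0.6744897501960817

NUTRIENT_FIELDS = ("energy_kj", "sugars_g", "sfa_g", "salt_g", "protein_g",
                   "fibre_g", "total_fat_g")


class NutrientSpec(BaseModel):
    """Target median and IQR width of one nutrient's log-normal law."""

    median: float = Field(gt=0)
    iqr: float = Field(ge=0)

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) matching the configured median and IQR exactly.

        For a log-normal law, P75 - P25 = 2 * median * sinh(Z75 * sigma),
        so sigma = asinh(iqr / (2 * median)) / Z75.
        """
        mu = math.log(self.median)
        sigma = math.asinh(self.iqr / (2.0 * self.median)) / _Z75
        return mu, sigma


class GroupSpec(BaseModel):
    """Market structure of one food group."""

    n_year1: int = Field(ge=0)
    n_year2: int = Field(ge=0)
    nutrients: dict[str, NutrientSpec]
    fibre_missing_p: float = Field(default=0.3, ge=0, le=1)
    fvl_missing_p: float = Field(default=1.0, ge=0, le=1)
    declared_fvl_pct: float = Field(default=0.0, ge=0, le=100)
    water_fraction: float = Field(default=0.0, ge=0, le=1)
    red_meat_rate: float = Field(default=0.0, ge=0, le=1)
    sweetener_rate: float = Field(default=0.0, ge=0, le=1)
    non_processed_rate: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _required_nutrients(self):
        required = {"energy_kj", "sugars_g", "sfa_g", "salt_g", "protein_g", "fibre_g"}
        missing = required - set(self.nutrients)
        if missing:
            raise ValueError(f"nutrient specs missing for {sorted(missing)}")
        unknown = set(self.nutrients) - set(NUTRIENT_FIELDS)
        if unknown:
            raise ValueError(f"unknown nutrient fields {sorted(unknown)}")
        return self


class ReformulationShift(BaseModel):
    """Composition shift applied to carried-over products of one group."""

    food_group: str
    nutrient: str
    delta: float = 0.0          # additive change (g or kJ per 100 g/mL)
    factor: float = 1.0         # multiplicative change, applied before delta
    fraction: float = Field(default=1.0, ge=0, le=1)  # share of carried products hit


class DiversificationShift(BaseModel):
    """Median shift of the sampling law for new year-2 products of a group."""

    food_group: str
    nutrient: str
    median_factor: float = Field(gt=0)


class SyntheticConfig(BaseModel):
    """Everything the generator needs to build two snapshots."""

    year1: int = 2018
    year2: int = 2020
    groups: dict[str, GroupSpec]
    carry_over: float = Field(default=0.6, ge=0, le=1)
    reformulation: list[ReformulationShift] = Field(default_factory=list)
    diversification: list[DiversificationShift] = Field(default_factory=list)
    seed: int = 0


def _truncate(nutrient: str, values: np.ndarray) -> np.ndarray:
    values = np.maximum(values, 0.0)
    if nutrient == "sugars_g":
        values = np.minimum(values, 100.0)
    return values


def _sample_compositions(
    spec: GroupSpec, n: int, rng: np.random.Generator,
    median_factors: Optional[dict[str, float]] = None,
) -> dict[str, np.ndarray]:
    """Draw n composition vectors (independent log-normals per nutrient)."""
    out: dict[str, np.ndarray] = {}
    for nutrient, law in spec.nutrients.items():
        mu, sigma = law.lognormal_params()
        if median_factors and nutrient in median_factors:
            mu += math.log(median_factors[nutrient])
        draws = rng.lognormal(mean=mu, sigma=sigma, size=n) if sigma > 0 else (
            np.full(n, math.exp(mu))
        )
        out[nutrient] = _truncate(nutrient, draws)
    if "total_fat_g" in out:
        # keep SFA physically consistent with total fat
        out["sfa_g"] = np.minimum(out["sfa_g"], out["total_fat_g"])
    return out


def _build_records(
    group: str,
    spec: GroupSpec,
    year: int,
    eans: list[str],
    comps: dict[str, np.ndarray],
    rng: np.random.Generator,
    taxonomy: FoodGroupTaxonomy,
) -> list[FoodRecord]:
    n = len(eans)
    is_beverage = taxonomy.category_for(group) == "beverage"
    water = rng.random(n) < spec.water_fraction if is_beverage else np.zeros(n, bool)
    red_meat = rng.random(n) < spec.red_meat_rate
    sweet = rng.random(n) < spec.sweetener_rate if is_beverage else np.zeros(n, bool)
    fibre_missing = rng.random(n) < spec.fibre_missing_p
    fvl_missing = rng.random(n) < spec.fvl_missing_p
    non_processed = rng.random(n) < spec.non_processed_rate

    records = []
    for i, ean in enumerate(eans):
        ingredients = []
        if red_meat[i]:
            ingredients.append("varkensvlees")
        if sweet[i]:
            ingredients.append("aspartame")
        if water[i]:
            name = f"mineral water {ean}"
            comp = {k: 0.0 for k in NUTRIENT_FIELDS}
        else:
            name = f"{group} product {ean}"
            comp = {k: float(comps[k][i]) for k in comps}
        records.append(
            FoodRecord(
                ean=ean,
                name=name,
                ingredients=", ".join(ingredients),
                food_group=group,
                year=year,
                energy_kj=comp.get("energy_kj", 0.0),
                sugars_g=comp.get("sugars_g", 0.0),
                sfa_g=comp.get("sfa_g", 0.0),
                salt_g=comp.get("salt_g", 0.0),
                protein_g=comp.get("protein_g", 0.0),
                fibre_g=None if fibre_missing[i] else comp.get("fibre_g", 0.0),
                fvl_pct=None if fvl_missing[i] else spec.declared_fvl_pct,
                total_fat_g=comp.get("total_fat_g"),
                is_water=bool(water[i]),
                is_processed=not bool(non_processed[i]),
            )
        )
    return records


def inject_reformulation(
    records: list[FoodRecord],
    shifts: list[ReformulationShift],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[FoodRecord], pd.DataFrame]:
    """Apply composition shifts to (a fraction of) each group's products.

    Returns the shifted records and a truth table with one row per
    (product, nutrient) shift actually applied: EAN, group, nutrient, the
    value before and after (shifts truncate at zero, sugars at 100).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_group: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_group.setdefault(r.food_group, []).append(i)

    out = list(records)
    truth_rows = []
    for shift in shifts:
        idxs = by_group.get(shift.food_group, [])
        if not idxs:
            continue
        n_hit = int(round(shift.fraction * len(idxs)))
        hit = sorted(rng.choice(idxs, size=n_hit, replace=False).tolist())
        for i in hit:
            rec = out[i]
            before = getattr(rec, shift.nutrient)
            if before is None:
                continue
            after = float(
                _truncate(shift.nutrient,
                          np.array([before * shift.factor + shift.delta]))[0]
            )
            out[i] = rec.model_copy(update={shift.nutrient: after})
            truth_rows.append(
                {
                    "ean": rec.ean,
                    "food_group": rec.food_group,
                    "nutrient": shift.nutrient,
                    "value_before": before,
                    "value_after": after,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["ean", "food_group", "nutrient", "value_before", "value_after"],
    )
    return out, truth


def generate_snapshots(
    config: SyntheticConfig, taxonomy: Optional[FoodGroupTaxonomy] = None
) -> tuple[list[FoodRecord], list[FoodRecord], pd.DataFrame]:
    """Build the two market snapshots and the reformulation truth table.

    Year 2 consists of carried-over year-1 products (same EAN; composition
    identical unless a reformulation shift hits them) plus newly introduced
    products drawn from the group's law, median-shifted where a
    diversification spec says so.  Fully reproducible from ``config.seed``;
    per-group streams are derived deterministically so adding a group does
    not reshuffle the others.
    """
    if taxonomy is None:
        taxonomy = FoodGroupTaxonomy.default()
    for group in config.groups:
        if group not in taxonomy:
            raise ValueError(f"synthetic config references unknown group {group!r}")

    records1: list[FoodRecord] = []
    carried: list[FoodRecord] = []
    new2: list[FoodRecord] = []

    group_keys = sorted(config.groups)
    for gi, group in enumerate(group_keys):
        spec = config.groups[group]
        seed_seq = np.random.SeedSequence([config.seed, gi])
        rng_y1, rng_y2, rng_carry = [
            np.random.default_rng(s) for s in seed_seq.spawn(3)
        ]

        eans1 = [f"87{gi:03d}{serial:08d}" for serial in range(spec.n_year1)]
        comps1 = _sample_compositions(spec, spec.n_year1, rng_y1)
        group_records1 = _build_records(
            group, spec, config.year1, eans1, comps1, rng_y1, taxonomy
        )
        records1.extend(group_records1)

        n_carry = min(int(round(config.carry_over * spec.n_year1)), spec.n_year2)
        carry_idx = sorted(
            rng_carry.choice(spec.n_year1, size=n_carry, replace=False).tolist()
        ) if spec.n_year1 else []
        for i in carry_idx:
            carried.append(group_records1[i].model_copy(update={"year": config.year2}))

        n_new = spec.n_year2 - n_carry
        div_factors = {
            d.nutrient: d.median_factor
            for d in config.diversification
            if d.food_group == group
        }
        eans2 = [f"87{gi:03d}{serial:08d}" for serial in
                 range(spec.n_year1, spec.n_year1 + n_new)]
        comps2 = _sample_compositions(spec, n_new, rng_y2, div_factors or None)
        new2.extend(
            _build_records(group, spec, config.year2, eans2, comps2, rng_y2, taxonomy)
        )

    rng_shift = np.random.default_rng(np.random.SeedSequence([config.seed, 10_007]))
    carried, truth = inject_reformulation(carried, config.reformulation, rng_shift)

    records2 = carried + new2
    return records1, records2, truth


def recovery_config(seed: int = 0, n_per_group: int = 2000) -> SyntheticConfig:
    """The parameter-recovery experiment: five solid-food groups, two of
    them with injected sugar reformulation.

    Fibre is fully declared and the fruit/vegetable/legume share is always
    estimated from the taxonomy here, so carried-over products that were
    not reformulated are bit-identical across the two years and the only
    class changes among matched EANs are those listed in the truth table.
    (Per-year mean imputation of missing fibre is exercised by its own
    tests; mixing it in would blur the construction-based expectation.)

    Dispersions are chosen for identifiability: the sample median of a
    log-normal has relative standard error ~1.25*sigma/sqrt(n), so every
    checked nutrient keeps sigma <= ~0.45, which at n = 2000 puts a 5%
    recovery band at four or more standard errors.
    """

    def law(**kw):
        return {k: NutrientSpec(median=m, iqr=w) for k, (m, w) in kw.items()}

    def group(nutrients):
        return GroupSpec(
            n_year1=n_per_group, n_year2=n_per_group,
            fibre_missing_p=0.0, fvl_missing_p=1.0,
            nutrients=nutrients,
        )

    groups = {
        "breakfast_cereals": group(law(
            energy_kj=(1600, 330), sugars_g=(17, 10), sfa_g=(1.4, 0.8),
            salt_g=(0.4, 0.24), protein_g=(9, 4), fibre_g=(7, 3))),
        "dairy_plant_solid": group(law(
            energy_kj=(450, 260), sugars_g=(10, 6), sfa_g=(2.2, 1.2),
            salt_g=(0.12, 0.07), protein_g=(4.5, 2.4), fibre_g=(0.5, 0.3))),
        "sweets_sweet_goods": group(law(
            energy_kj=(1900, 700), sugars_g=(45, 25), sfa_g=(4.8, 2.8),
            salt_g=(0.15, 0.09), protein_g=(4, 2.2), fibre_g=(2, 1.1))),
        "bread_substitutes": group(law(
            energy_kj=(1400, 420), sugars_g=(4, 2.2), sfa_g=(0.8, 0.45),
            salt_g=(1.1, 0.4), protein_g=(9, 3), fibre_g=(5, 2.6))),
        "cheeses": group(law(
            energy_kj=(1400, 430), sugars_g=(0.8, 0.45), sfa_g=(15, 8),
            salt_g=(1.7, 0.7), protein_g=(22, 6), fibre_g=(0.1, 0.05))),
    }
    reformulation = [
        ReformulationShift(food_group="breakfast_cereals", nutrient="sugars_g",
                           delta=-6.0, fraction=0.6),
        ReformulationShift(food_group="dairy_plant_solid", nutrient="sugars_g",
                           delta=-4.0, fraction=0.6),
    ]
    return SyntheticConfig(
        groups=groups, carry_over=0.5, reformulation=reformulation, seed=seed
    )


def demo_config(scale: float = 1.0, seed: int = 0) -> SyntheticConfig:
    """A realistic default market: eight groups, label-like nutrient laws.

    Group sizes grow ~25% between snapshots (market diversification);
    roughly a third of products lack a declared fibre content and almost
    none declare a fruit/vegetable/legume share.  Two groups carry modest
    sugar reformulation, mirroring the kind of change reformulation
    monitoring looks for.  ``scale`` multiplies every group size.
    """

    def n(base: int) -> int:
        return max(int(round(base * scale)), 12)

    groups = {
        "breakfast_cereals": GroupSpec(
            n_year1=n(250), n_year2=n(320),
            nutrients={
                "energy_kj": NutrientSpec(median=1600, iqr=330),
                "sugars_g": NutrientSpec(median=17, iqr=11),
                "sfa_g": NutrientSpec(median=1.4, iqr=1.6),
                "salt_g": NutrientSpec(median=0.4, iqr=0.5),
                "protein_g": NutrientSpec(median=9, iqr=4),
                "fibre_g": NutrientSpec(median=7, iqr=4),
            },
        ),
        "sweets_sweet_goods": GroupSpec(
            n_year1=n(400), n_year2=n(520),
            nutrients={
                "energy_kj": NutrientSpec(median=1900, iqr=700),
                "sugars_g": NutrientSpec(median=45, iqr=25),
                "sfa_g": NutrientSpec(median=4.8, iqr=8),
                "salt_g": NutrientSpec(median=0.15, iqr=0.2),
                "protein_g": NutrientSpec(median=4, iqr=3),
                "fibre_g": NutrientSpec(median=2, iqr=2),
            },
        ),
        "meat_preserves": GroupSpec(
            n_year1=n(150), n_year2=n(180),
            red_meat_rate=0.55,
            nutrients={
                "energy_kj": NutrientSpec(median=1000, iqr=420),
                "sugars_g": NutrientSpec(median=1.5, iqr=2),
                "sfa_g": NutrientSpec(median=7, iqr=5),
                "salt_g": NutrientSpec(median=2.0, iqr=0.8),
                "protein_g": NutrientSpec(median=13, iqr=5),
                "fibre_g": NutrientSpec(median=0.5, iqr=0.7),
            },
        ),
        "dairy_plant_solid": GroupSpec(
            n_year1=n(300), n_year2=n(330),
            nutrients={
                "energy_kj": NutrientSpec(median=450, iqr=260),
                "sugars_g": NutrientSpec(median=10, iqr=6),
                "sfa_g": NutrientSpec(median=2.2, iqr=2.6),
                "salt_g": NutrientSpec(median=0.12, iqr=0.1),
                "protein_g": NutrientSpec(median=4.5, iqr=3),
                "fibre_g": NutrientSpec(median=0.5, iqr=1),
            },
        ),
        "dairy_plant_beverages": GroupSpec(
            n_year1=n(160), n_year2=n(190),
            sweetener_rate=0.12,
            nutrients={
                "energy_kj": NutrientSpec(median=250, iqr=130),
                "sugars_g": NutrientSpec(median=6.9, iqr=4),
                "sfa_g": NutrientSpec(median=1.0, iqr=1.2),
                "salt_g": NutrientSpec(median=0.12, iqr=0.08),
                "protein_g": NutrientSpec(median=3.3, iqr=1),
                "fibre_g": NutrientSpec(median=0.4, iqr=0.6),
            },
        ),
        "bread_substitutes": GroupSpec(
            n_year1=n(280), n_year2=n(420),
            nutrients={
                "energy_kj": NutrientSpec(median=1400, iqr=420),
                "sugars_g": NutrientSpec(median=4, iqr=4),
                "sfa_g": NutrientSpec(median=0.8, iqr=1),
                "salt_g": NutrientSpec(median=1.1, iqr=0.4),
                "protein_g": NutrientSpec(median=9, iqr=3),
                "fibre_g": NutrientSpec(median=5, iqr=3),
            },
        ),
        "cheeses": GroupSpec(
            n_year1=n(300), n_year2=n(280),
            nutrients={
                "energy_kj": NutrientSpec(median=1400, iqr=430),
                "sugars_g": NutrientSpec(median=0.5, iqr=1.2),
                "sfa_g": NutrientSpec(median=15, iqr=8),
                "salt_g": NutrientSpec(median=1.7, iqr=0.7),
                "protein_g": NutrientSpec(median=22, iqr=6),
                "fibre_g": NutrientSpec(median=0.1, iqr=0.15),
            },
        ),
        "soft_drinks": GroupSpec(
            n_year1=n(220), n_year2=n(260),
            water_fraction=0.12, sweetener_rate=0.3,
            nutrients={
                "energy_kj": NutrientSpec(median=120, iqr=110),
                "sugars_g": NutrientSpec(median=7, iqr=6),
                "sfa_g": NutrientSpec(median=0.05, iqr=0.05),
                "salt_g": NutrientSpec(median=0.02, iqr=0.03),
                "protein_g": NutrientSpec(median=0.1, iqr=0.1),
                "fibre_g": NutrientSpec(median=0.05, iqr=0.08),
            },
        ),
    }
    reformulation = [
        ReformulationShift(
            food_group="breakfast_cereals", nutrient="sugars_g",
            delta=-3.5, fraction=0.35,
        ),
        ReformulationShift(
            food_group="dairy_plant_beverages", nutrient="sugars_g",
            delta=-2.2, fraction=0.4,
        ),
    ]
    diversification = [
        DiversificationShift(
            food_group="breakfast_cereals", nutrient="sugars_g", median_factor=0.85
        ),
    ]
    return SyntheticConfig(
        groups=groups,
        carry_over=0.6,
        reformulation=reformulation,
        diversification=diversification,
        seed=seed,
    )
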