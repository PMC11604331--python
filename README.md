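# nutriscope

Nutrient profiling and food-supply monitoring with the **updated Nutri-Score
algorithm** (solid foods, 2022 update; beverages, 2023 update).

Nutri-Score is the five-class front-of-pack nutrition label (A, dark green,
to E, dark orange) used across a growing number of European countries.
Public-health institutes monitor branded-food databases — one row per
product per year with label-declared composition per 100 g (per 100 mL for
beverages) — to ask whether manufacturers reformulate products, and whether
those reformulations are large enough to move products into a better class.
`nutriscope` is a toolkit for exactly that workflow: it scores snapshots of
a retail food supply, prepares label data the standard way, and compares
two market years.

## The algorithm

For each product the algorithm allocates **negative points** *N* to
unfavourable components — energy (kJ), sugars (g), saturated fatty acids
(g; for fats, oils, nuts and seeds the ratio 100·SFA/total fat), salt (g) —
and **positive points** *P* to favourable ones — protein (g), fibre (g),
and the fruit/vegetable/legume share FVL (%). Each component's points come
from a step-function grid of ascending cutoffs. The final sum is

```
final_sum = N − P_applied
```

where protein is dropped from *P* when *N* ≥ 11 for general solid foods
(*N* ≥ 7 for fats/oils/nuts/seeds) unless the product earns maximal FVL
points or is a cheese. Red-meat products have protein points capped at 2;
beverages with non-nutritive sweeteners receive 4 extra negative points.
The final sum maps to the class letter; for general solid foods A ≤ 0,
B = 1–2, C = 3–10, D = 11–18, E ≥ 19. Among beverages only mineral waters
receive class A.

The complete point grids, class bounds, special rules and keyword lists
live in an editable YAML scheme
(`src/nutriscope/data/scheme_2023.yaml`), transcribed from the official
updated-algorithm documents, so the engine is data-driven and auditable.

## Worked example

```python
from nutriscope import FoodRecord, ScoringScheme, FoodGroupTaxonomy, score_record

scheme   = ScoringScheme.default()
taxonomy = FoodGroupTaxonomy.default()

cereal = FoodRecord(
    ean="8712345678901", name="crunchy muesli",
    food_group="breakfast_cereals", year=2020,
    energy_kj=1600, sugars_g=17, sfa_g=1.4, salt_g=0.4,
    protein_g=9, fibre_g=7, fvl_pct=5,
)
result = score_record(cereal, scheme, taxonomy)
print(result.points)
print(result.negative_sum, result.positive_sum, result.final_sum, result.nutri_class)
```

prints

```
{'energy': 4, 'sugars': 4, 'sfa': 1, 'salt': 1, 'protein': 3, 'fibre': 4, 'fvl': 0}
10 7 3 C
```

Energy (1600 kJ) and sugars (17 g/100 g) each earn 4 negative points, SFA
and salt 1 each, so *N* = 10; protein earns 3, fibre 4 and FVL 0 positive
points and protein is counted because *N* < 11, so *P* = 7. The final sum
10 − 7 = 3 falls in the 3–10 band: class **C**. Cutting sugars to
13.5 g/100 g would remove two sugar points and lift the product to
final sum 1, class B — the kind of reformulation headroom the comparison
pipeline quantifies market-wide.

## Comparing two market snapshots

```bash
nutriscope simulate runs/sim --seed 1          # synthetic two-year market + truth table
nutriscope compare runs/sim/snapshot_2018.csv runs/sim/snapshot_2020.csv runs/report
```

`compare` prepares each year (keeps processed foods, drops records missing
a mandatory component, imputes missing fibre with the group-year mean,
assigns per-group FVL estimates, drops group-years under 10 products),
scores every product and writes: per-group median/IQR nutrient tables,
class distributions with percentage-point changes and the top-5
most-changed groups, per-class nutrient medians for those groups, a
matched-EAN sensitivity analysis (products sold in both years), final-sum
histograms (CSV + PNG), and a run log recording the scheme hash and every
convention used. Since real branded-food databases are proprietary, the
`simulate` subcommand generates snapshots with the same statistical
structure (log-normal nutrient laws parameterised by median/IQR, fibre
missingness, EAN carry-over, injected reformulation, diversification) for
development and validation.

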