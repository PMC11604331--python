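# Methods

## Scope and model

`nutriscope` implements the updated Nutri-Score nutrient-profiling
algorithm (solid-food update adopted 2022, beverage update adopted 2023)
and a two-snapshot market-comparison pipeline of the kind used in food
reformulation monitoring. The unit of analysis is a branded product's
label declaration: composition per 100 g (per 100 mL for beverages), a
food-group assignment, and free-text name/ingredients. The algorithm is a
deterministic step-function profile: negative points for energy, sugars,
saturated fat (SFA; for fats/oils/nuts/seeds the SFA/total-fat ratio) and
salt; positive points for protein, fibre and the fruit/vegetable/legume
share (FVL); `final_sum = N − P_applied`; class letters from
category-specific integer bands. All grids, bands and special rules
(red-meat protein cap of 2 points, cheese protein exemption, 4-point
beverage sweetener penalty, water → A) are data, shipped as YAML
transcribed from the official updated-algorithm documents of Santé
publique France / the International Scientific Committee of Nutri-Score,
and validated in tests against four algorithm-constant anchors: class C
for general solids is exactly 3–10, class B exactly 1–2 (so the worst-case
C→B improvement is 8 points), and only mineral waters reach class A among
beverages.

The pre-2022 algorithm and the UK FSA profiling system are deliberately
out of scope.

## Boundary convention

Official grid tables use a strictly-greater reading (a value earns the
points of the highest cutoff it *exceeds*); `component_points` defaults to
this `strict` convention. A single switch selects an `inclusive` (≥)
reading. The distinction matters exactly on cutoffs: on the general-solid
sugars grid, 17 g/100 g earns 4 points under `strict` but 5 under
`inclusive`, so the often-quoted "17 → 13.5 g removes two sugar points"
example holds under the inclusive reading and only one point under the
strict one. The package records the convention of every run in the
pipeline log and never alters the transcribed grids.

## Data preparation

The preparation pipeline runs in a fixed, logged order:

1. keep processed foods (the flag is input data, not inferred);
2. exclude records missing any mandatory component (energy, salt, SFA,
   sugars, protein) — fibre or FVL missingness never excludes;
3. impute missing fibre with the arithmetic mean of observed fibre in the
   same food group *and year* (fibre declaration is not mandatory on EU
   labels, so missingness is common and structural); a group-year with no
   observed fibre at all is an error rather than a silent zero;
4. assign each record without a declared FVL share its food group's
   configured estimate (FVL is not label-declared, so group-level
   estimates are the operational standard);
5. drop group-years with fewer than 10 products (default, configurable).

Every step's counts are returned in a report whose totals reconcile
(input = retained + excluded). Salt is the stored quantity; sodium inputs
are converted at ingest (salt = 2.5 × sodium) and logged. Energy is kJ;
kcal sources should be converted at 4.184 kJ/kcal before ingest.

## Comparison statistics

Per group-year the pipeline reports n, median and IQR (P25–P75) per
nutrient, the class distribution in percent, the mean final sum, and
integer-binned final-sum histograms. Conventions: the median of an even
group is the midpoint of the two central order statistics; percentiles use
linear interpolation; percentages are full-precision internally and
rounded only for display. Class-distribution change is `year2 − year1` in
percentage points per class (rows sum to 0 by construction); the scalar
"overall change" of a group is Σ|Δpp|/2 — total variation, i.e. the
percentage of the group's mass that changed class — with the raw Σ|Δpp|
variant available by option, since the field's prose ("largest change in
percentage points over all classifications") does not pin down the metric.
Top-k selection sorts by this scalar with ties broken by group key, so
selections are deterministic. The matched-EAN sensitivity analysis
inner-joins the two years on EAN (duplicates within a year are an error),
counts a product as changed only when its class *letter* differs (a
final-sum change within a class is no change), and groups by the earlier
year's food group. Groups observed in only one year are excluded from
change statistics — a change is undefined for them. No inferential
statistics are computed; the design is a census of the available market,
not a sample.

## Synthetic market generator

Real branded-food databases are proprietary, so the generator builds
snapshots with the structure the analysis assumes: per-group, per-nutrient
log-normal laws parameterised *directly* by target median m and IQR w
(σ = asinh(w/2m)/z₀.₇₅, μ = ln m — exact, no fitting), truncated at 0 and
at 100 g for sugars; independent nutrients; configurable fibre/FVL
missingness; EAN carry-over between years (carried products keep their
composition bit-for-bit unless a reformulation shift hits them);
reformulation specs (additive/multiplicative shifts on a fraction of
carried products, with a truth table of every applied shift);
diversification specs (median shifts for newly introduced year-2
products); mineral-water fractions in beverage groups; and keyword
injection for red meat and sweeteners. A single master seed drives
per-group child streams, so output is reproducible and adding a group
does not reshuffle the others.

The default demo market has eight groups of ~100–500 products with
label-realistic medians and IQRs, year-2 growth of ~25%, ~30% fibre
missingness, FVL almost never declared, and modest sugar reformulation in
two groups. What the generator does *not* emulate: correlations between
nutrients within a product, brand structure, price/market-share weights,
seasonal assortment churn, or label rounding. Tests passing on synthetic
data therefore validate the pipeline's logic and statistics, not any claim
about a real market.

## The parameter-recovery experiment

`recovery_config()` defines the validation experiment: five solid-food
groups × 2000 products per year, carry-over 0.5, and sugar shifts
(−6 g/100 g on 60% of carried breakfast cereals, −4 g/100 g on 60% of
carried dairy/plant solid foods). Design choices, made a priori:

- **Identifiability.** The sample median of a log-normal has relative
  standard error ≈ 1.25σ/√n, so every checked nutrient keeps σ ≤ ~0.45;
  at n = 2000 a 5% recovery band is then ≥ 4 standard errors wide.
- **Medians are checked for the five mandatory nutrients.** Fibre is
  excluded from the recovery check because group-mean imputation
  intentionally replaces missing values and thereby shifts the group
  median — that is a property of the imputation rule, not a generator
  defect.
- **Fibre is fully declared in this experiment** (missingness is covered
  by its own tests). With per-year imputation, an unreformulated
  carried-over product could otherwise change class merely because the
  two years' imputation means differ; switching missingness off makes the
  truth table the *exact* list of products that can change class, so the
  matched-EAN change shares can be required to equal a per-record
  rescoring of carried pairs exactly, not approximately.

The experiment (~20 000 products) runs in seconds; the full test suite in
well under a minute.

## Numerical and degenerate-input choices

- Final sums are integers by construction; `classify` rejects
  non-integers rather than rounding.
- Scoring is pure: identical inputs give identical `ScoreResult`s;
  pipeline re-runs produce byte-identical CSVs (floats are written as
  shortest round-trip `repr` and read back with round-trip precision).
- A fats/oils/nuts/seeds record without total fat cannot be scored
  (ratio undefined) and errors; total fat 0 is scored as ratio 0.
- Missing values are empty CSV cells, never 0 — 0 is a legal content.
- Keyword detection lower-cases and strips diacritics before substring
  matching; the shipped red-meat/sweetener lists are editable defaults
  (the mechanism, term search over name + ingredients, is standard; the
  exact term lists are a per-study choice).
- An empty food group in a summary or histogram is an error or an absent
  row, never a fabricated zero.

## Limitations

- The full 21-group taxonomy with per-group FVL estimates is a
  configurable default; the estimates shipped are plausible placeholders
  to be replaced with study-specific values.
- The cheese protein exemption and red-meat cap are taken from the
  official guideline documents; products are flagged by group membership
  (cheese) and keyword search (red meat), both of which are cruder than a
  curated product-level classification.
- Group-mean fibre imputation and group-level FVL estimates bias
  individual scores toward the group centre; class distributions are
  correspondingly smoothed. This mirrors standard practice when labels
  lack the fields, but per-class medians for fibre-driven groups should
  be read with care.
- The generator's independence assumption between nutrients understates
  the real covariance of, e.g., sugar and energy; recovered class
  distributions are structurally realistic, not market-calibrated.
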