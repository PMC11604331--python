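# Default food-group taxonomy for branded-food snapshots, modelled on the
# group structure of the Dutch reformulation-monitoring programme, with the
# dairy and plant-based group split into solid foods and beverages (the two
# are scored by different Nutri-Score algorithms).
#
# fvl_estimate: default fruits/vegetables/legumes percentage assigned to
# products of the group when the label does not declare one.  These are
# package defaults chosen as plausible values for each group and are meant
# to be edited per study.

groups:
  - key: bread_substitutes
    name: "Bread (substitutes)"
    category: general_solid
    fvl_estimate: 0
  - key: breakfast_cereals
    name: "Breakfast cereals"
    category: general_solid
    fvl_estimate: 5
  - key: cheeses
    name: "Cheeses"
    category: general_solid
    fvl_estimate: 0
  - key: baked_goods_pastries
    name: "Baked goods and pastries"
    category: general_solid
    fvl_estimate: 0
  - key: sweets_sweet_goods
    name: "Sweets and sweet goods"
    category: general_solid
    fvl_estimate: 0
  - key: dairy_plant_solid
    name: "Dairy and plant-based solid foods"
    category: general_solid
    fvl_estimate: 5
  - key: dairy_plant_beverages
    name: "Dairy and plant-based beverages"
    category: beverage
    fvl_estimate: 0
  - key: soft_drinks
    name: "Soft drinks and juices"
    category: beverage
    fvl_estimate: 20
  - key: meat_preserves
    name: "Meat preserves"
    category: general_solid
    fvl_estimate: 0
  - key: cold_cut_meats
    name: "Cold-cut meats"
    category: general_solid
    fvl_estimate: 0
  - key: meat_substitutes
    name: "Meat substitutes"
    category: general_solid
    fvl_estimate: 30
  - key: processed_legumes
    name: "Processed legumes"
    category: general_solid
    fvl_estimate: 80
  - key: vegetable_preserves
    name: "Vegetable preserves"
    category: general_solid
    fvl_estimate: 90
  - key: fruit_preserves
    name: "Fruit preserves"
    category: general_solid
    fvl_estimate: 90
  - key: cold_savoury_snacks
    name: "Cold savoury snacks"
    category: general_solid
    fvl_estimate: 10
  - key: pizzas
    name: "Pizzas"
    category: general_solid
    fvl_estimate: 15
  - key: soups
    name: "Soups"
    category: general_solid
    fvl_estimate: 40
  - key: sauces_condiments
    name: "Sauces and condiments"
    category: general_solid
    fvl_estimate: 25
  - key: savoury_spreads
    name: "Savoury spreads"
    category: general_solid
    fvl_estimate: 10
  - key: fats_and_oils
    name: "Fats and oils"
    category: fats_oils_nuts_seeds
    fvl_estimate: 0
  - key: nuts_and_seeds
    name: "Nuts and seeds"
    category: fats_oils_nuts_seeds
    fvl_estimate: 0
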