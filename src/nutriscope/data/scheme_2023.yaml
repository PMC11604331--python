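# Updated Nutri-Score scoring scheme (solid foods update adopted 2022,
# beverages update adopted 2023).
#
# Grids transcribed from the official updated-algorithm documents of the
# International Scientific Committee of Nutri-Score and the Santé publique
# France user guide.  The cheese protein exception and the red-meat protein
# cap are taken from those same guideline documents.
#
# Convention: a value earns the points of the highest cutoff it strictly
# exceeds ("strict"); the engine also supports an inclusive (">=") reading
# via the boundary_convention switch at scoring time.

name: nutri-score-2023
version: "2023"

categories:
  general_solid:
    grids:
      energy:       # kJ / 100 g
        cutoffs: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
      sugars:       # g / 100 g
        cutoffs: [3.4, 6.8, 10, 14, 17, 20, 24, 27, 31, 34, 37, 41, 44, 48, 51]
      sfa:          # g / 100 g
        cutoffs: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt:         # g / 100 g
        cutoffs: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                  2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
      protein:      # g / 100 g
        cutoffs: [2.4, 4.8, 7.2, 9.6, 12, 14, 17]
      fibre:        # g / 100 g
        cutoffs: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:          # % fruits, vegetables, legumes
        cutoffs: [40, 60, 80]
        points: [1, 2, 5]
    # protein points dropped when N >= 11, unless max FVL points or cheese
    protein_exclusion_threshold: 11
    fvl_exemption_points: 5
    class_bounds:   # closed integer intervals on the final sum; null = open end
      A: [null, 0]
      B: [1, 2]
      C: [3, 10]
      D: [11, 18]
      E: [19, null]

  fats_oils_nuts_seeds:
    grids:
      energy:       # kJ / 100 g, dedicated grid for this category
        cutoffs: [120, 240, 360, 480, 600, 720, 840, 960, 1080, 1200]
      sugars:
        cutoffs: [3.4, 6.8, 10, 14, 17, 20, 24, 27, 31, 34, 37, 41, 44, 48, 51]
      sfa_fat_ratio:  # 100 * SFA / total fat (%)
        cutoffs: [10, 16, 22, 28, 34, 40, 46, 52, 58, 64]
      salt:
        cutoffs: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                  2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
      protein:
        cutoffs: [2.4, 4.8, 7.2, 9.6, 12, 14, 17]
      fibre:
        cutoffs: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:
        cutoffs: [40, 60, 80]
        points: [1, 2, 5]
    protein_exclusion_threshold: 7
    fvl_exemption_points: 5
    class_bounds:
      A: [null, -6]
      B: [-5, 2]
      C: [3, 10]
      D: [11, 18]
      E: [19, null]

  beverage:
    grids:
      energy:       # kJ / 100 mL
        cutoffs: [30, 90, 150, 210, 240, 270, 300, 330, 360, 390]
      sugars:       # g / 100 mL
        cutoffs: [0.5, 2, 3.5, 5, 6, 7, 8, 9, 10, 11]
      sfa:
        cutoffs: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      salt:
        cutoffs: [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0,
                  2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
      protein:      # g / 100 mL
        cutoffs: [1.2, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0]
      fibre:
        cutoffs: [3.0, 4.1, 5.2, 6.3, 7.4]
      fvl:
        cutoffs: [40, 60, 80]
        points: [2, 4, 6]
    protein_exclusion_threshold: null   # protein always counted for beverages
    fvl_exemption_points: null
    class_bounds:   # class A is reachable only through the water rule
      B: [null, 2]
      C: [3, 6]
      D: [7, 9]
      E: [10, null]

special_rules:
  red_meat_protein_cap: 2      # max protein points for red meat products
  cheese_protein_always_counted: true
  sweetener_points: 4          # beverages with non-nutritive sweeteners
  water_class: A               # mineral waters are classified A outright

keywords:
  red_meat:
    - beef
    - rund
    - rundvlees
    - pork
    - varken
    - varkensvlees
    - lamb
    - lam
    - lamsvlees
    - veal
    - kalfsvlees
    - ham
    - bacon
    - spek
    - salami
    - chorizo
    - gehakt
  sweeteners:
    - aspartame
    - acesulfame
    - sucralose
    - saccharin
    - sacharine
    - cyclamate
    - cyclamaat
    - steviol
    - stevia
    - neotame
    - advantame
    - erythritol
    - xylitol
    - sorbitol
    - maltitol
    - zoetstof
    - sweetener
    - e950
    - e951
    - e952
    - e954
    - e955
    - e960
    - e961
    - e962
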