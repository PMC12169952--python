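# Default EAT-Lancet dietary index (EAT-I) component specification.
#
# Ten main components, 0-80 points total.  Adequacy components reward higher
# consumption up to the reference target; moderation components reward lower
# consumption (full points at or below the target, declining linearly to zero
# at `upper`); optional components give full points inside a plateau range
# and decline linearly to zero outside it.
#
# Targets are grams/day for a 2500 kcal reference diet (EAT-Lancet reference
# intakes; cut-offs for the declining arms are editable and chosen to span
# the plausible intake range).  `mapping` lists the intake variables (g/d)
# feeding each component, with multiplicative coefficients; the defaults
# match the synthetic food-group list shipped with this package and should
# be edited for any other food grouping.
reference_kcal: 2500
standardize_energy: true
components:
  - name: whole_grains
    kind: adequacy
    max_points: 10
    target: 232.0
    mapping: {whole_grains: 1000.0}
  - name: tubers_starchy_vegetables
    kind: moderation
    max_points: 10
    target: 50.0
    upper: 300.0
    mapping: {tubers: 1000.0}
  - name: vegetables
    kind: adequacy
    max_points: 10
    target: 300.0
    mapping: {vegetables: 1000.0}
  - name: fruits
    kind: adequacy
    max_points: 10
    target: 200.0
    mapping: {fruits: 1000.0}
  - name: dairy
    kind: optional
    max_points: 5
    plateau_low: 0.0
    plateau_high: 500.0
    zero_low: 0.0
    zero_high: 1000.0
    mapping: {dairy: 1000.0}
  - name: red_processed_meats
    kind: moderation
    max_points: 5
    target: 14.0
    upper: 100.0
    mapping: {red_processed_meat: 1000.0}
  - name: poultry_eggs
    kind: optional
    max_points: 5
    subcomponents:
      - name: poultry
        kind: optional
        max_points: 2.5
        plateau_low: 0.0
        plateau_high: 58.0
        zero_low: 0.0
        zero_high: 116.0
        mapping: {poultry_eggs: 700.0}
      - name: eggs
        kind: optional
        max_points: 2.5
        plateau_low: 0.0
        plateau_high: 25.0
        zero_low: 0.0
        zero_high: 50.0
        mapping: {poultry_eggs: 300.0}
  - name: fish_plant_proteins
    kind: adequacy
    max_points: 5
    subcomponents:
      - name: fish
        kind: adequacy
        max_points: 1.6666666666666667
        target: 28.0
        mapping: {fish_seafood: 1000.0}
      - name: legumes
        kind: adequacy
        max_points: 1.6666666666666667
        target: 75.0
        mapping: {legumes_nuts: 600.0}
      - name: nuts
        kind: adequacy
        max_points: 1.6666666666666666
        target: 50.0
        mapping: {legumes_nuts: 400.0}
  - name: added_fats
    kind: adequacy
    max_points: 10
    subcomponents:
      - name: saturated_fats
        kind: moderation
        max_points: 5
        target: 11.8
        upper: 40.0
        mapping: {added_fats_sat: 1000.0}
      - name: unsaturated_fats
        kind: adequacy
        max_points: 5
        target: 40.0
        mapping: {added_fats_unsat: 1000.0}
  - name: free_sugars
    kind: moderation
    max_points: 10
    target: 31.0
    upper: 124.0
    mapping: {sweets_sugary_drinks: 250.0}
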