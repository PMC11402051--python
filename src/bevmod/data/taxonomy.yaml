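# Beverage category rules keyed on the 4-digit WWEIA category code.
# A 2-digit prefix selects a subgroup, a 4-digit prefix a single category.
# requires_energy marks caloric-beverage categories: an item only matches
# when its energy is positive (plain water and diet drinks never match).
rules:
  - label: milk
    include_prefixes: ["10"]
    exclude_prefixes: []
    requires_energy: false
  - label: flavored_milk
    include_prefixes: ["12"]
    exclude_prefixes: []
    requires_energy: false
  - label: milk_substitutes
    include_prefixes: ["1404"]
    exclude_prefixes: []
    requires_energy: false
  - label: fruit_juice_100
    include_prefixes: ["70"]
    exclude_prefixes: []
    requires_energy: true
  - label: ssb
    include_prefixes: ["72"]
    exclude_prefixes: []
    requires_energy: true
  - label: soft_drinks
    include_prefixes: ["7202"]
    exclude_prefixes: []
    requires_energy: true
  - label: fruit_drinks
    include_prefixes: ["7204"]
    exclude_prefixes: []
    requires_energy: true
  - label: coffee_tea
    include_prefixes: ["73"]
    exclude_prefixes: []
    requires_energy: true
  # Caloric beverages excluding milk: the whole beverage main group with
  # positive energy, minus non-caloric / diet / water subgroups.  Milk,
  # flavored milk and milk substitutes live outside this prefix space, so
  # they are excluded by construction.
  - label: cb
    include_prefixes: ["7"]
    exclude_prefixes: ["71", "77", "78"]
    requires_energy: true
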