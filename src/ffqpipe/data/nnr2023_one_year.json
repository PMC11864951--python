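{
  "description": "Nordic Nutrition Recommendation cutoffs for children around one year of age, as applied to whole-diet intakes. Bases: absolute daily amount, nutrient density per MJ, or percentage of energy (E%). Rules with an age_variant apply only when classification is run for that variant; the iodine adequate intake is given as a range 80-90 ug and encoded at its midpoint 85 ug.",
  "rules": [
    {"rule_id": "carbohydrate_epct", "label": "Carbohydrates", "nutrient": "carbohydrate_epct", "basis": "energy_percent", "direction": "within", "low": 45, "high": 60, "unit": "E%", "rule_class": "RI"},
    {"rule_id": "fat_epct", "label": "Fat", "nutrient": "fat_epct", "basis": "energy_percent", "direction": "within", "low": 30, "high": 45, "unit": "E%", "rule_class": "RI"},
    {"rule_id": "protein_epct", "label": "Protein", "nutrient": "protein_epct", "basis": "energy_percent", "direction": "within", "low": 7, "high": 15, "unit": "E%", "rule_class": "RI"},
    {"rule_id": "omega3_infant", "label": "Omega-3 fatty acids", "nutrient": "omega3_epct", "basis": "energy_percent", "direction": "at_least", "threshold": 1.0, "unit": "E%", "rule_class": "RI", "age_variant": "infant_le_11m"},
    {"rule_id": "omega3_1_3y", "label": "Omega-3 fatty acids", "nutrient": "omega3_epct", "basis": "energy_percent", "direction": "at_least", "threshold": 0.5, "unit": "E%", "rule_class": "RI", "age_variant": "child_1_3y"},
    {"rule_id": "omega6", "label": "Omega-6 fatty acids", "nutrient": "omega6_epct", "basis": "energy_percent", "direction": "at_least", "threshold": 4.0, "unit": "E%", "rule_class": "RI"},
    {"rule_id": "sfa", "label": "Saturated fat", "nutrient": "sfa_epct", "basis": "energy_percent", "direction": "at_most", "threshold": 10.0, "strict": true, "unit": "E%", "rule_class": "upper_guideline"},
    {"rule_id": "trans_fat", "label": "Trans fat", "nutrient": "trans_epct", "basis": "energy_percent", "direction": "as_low_as_possible", "unit": "E%", "rule_class": "upper_guideline"},
    {"rule_id": "niacin", "label": "Niacin", "nutrient": "niacin_eq_mg", "basis": "per_MJ", "direction": "at_least", "threshold": 1.6, "unit": "NE/MJ", "rule_class": "RI"},
    {"rule_id": "thiamine", "label": "Thiamine", "nutrient": "thiamine_mg", "basis": "per_MJ", "direction": "at_least", "threshold": 0.1, "unit": "mg/MJ", "rule_class": "RI"},
    {"rule_id": "vitamin_b6", "label": "Vitamin B6", "nutrient": "vitamin_b6_mg", "basis": "absolute", "direction": "at_least", "threshold": 0.4, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "zinc", "label": "Zinc", "nutrient": "zinc_mg", "basis": "absolute", "direction": "at_least", "threshold": 3.0, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "vitamin_a", "label": "Vitamin A", "nutrient": "vitamin_a_ug", "basis": "absolute", "direction": "at_least", "threshold": 250, "unit": "ug", "rule_class": "RI"},
    {"rule_id": "folate", "label": "Folate", "nutrient": "folate_ug", "basis": "absolute", "direction": "at_least", "threshold": 90, "unit": "ug", "rule_class": "RI"},
    {"rule_id": "iron", "label": "Iron", "nutrient": "iron_mg", "basis": "absolute", "direction": "at_least", "threshold": 10, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "vitamin_d", "label": "Vitamin D", "nutrient": "vitamin_d_ug", "basis": "absolute", "direction": "at_least", "threshold": 10, "unit": "ug", "rule_class": "RI"},
    {"rule_id": "sodium_infant", "label": "Sodium", "nutrient": "sodium_mg", "basis": "absolute", "direction": "at_most", "threshold": 370, "unit": "mg", "rule_class": "upper_guideline", "age_variant": "infant_le_11m"},
    {"rule_id": "sodium_1_3y", "label": "Sodium", "nutrient": "sodium_mg", "basis": "absolute", "direction": "at_most", "threshold": 1100, "unit": "mg", "rule_class": "upper_guideline", "age_variant": "child_1_3y"},
    {"rule_id": "phosphorus", "label": "Phosphorus", "nutrient": "phosphorus_mg", "basis": "absolute", "direction": "at_least", "threshold": 170, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "potassium", "label": "Potassium", "nutrient": "potassium_mg", "basis": "absolute", "direction": "at_least", "threshold": 700, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "magnesium", "label": "Magnesium", "nutrient": "magnesium_mg", "basis": "absolute", "direction": "at_least", "threshold": 80, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "riboflavin", "label": "Riboflavin", "nutrient": "riboflavin_mg", "basis": "absolute", "direction": "at_least", "threshold": 0.4, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "vitamin_c", "label": "Vitamin C", "nutrient": "vitamin_c_mg", "basis": "absolute", "direction": "at_least", "threshold": 30, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "calcium", "label": "Calcium", "nutrient": "calcium_mg", "basis": "absolute", "direction": "at_least", "threshold": 310, "unit": "mg", "rule_class": "RI"},
    {"rule_id": "vitamin_b12", "label": "Vitamin B12", "nutrient": "vitamin_b12_ug", "basis": "absolute", "direction": "at_least", "threshold": 1.5, "unit": "ug", "rule_class": "RI"},
    {"rule_id": "vitamin_e", "label": "Vitamin E", "nutrient": "vitamin_e_mg", "basis": "absolute", "direction": "at_least", "threshold": 5, "unit": "mg", "rule_class": "AI"},
    {"rule_id": "vitamin_k", "label": "Vitamin K", "nutrient": "vitamin_k_ug", "basis": "absolute", "direction": "at_least", "threshold": 10, "unit": "ug", "rule_class": "AI"},
    {"rule_id": "iodine", "label": "Iodine", "nutrient": "iodine_ug", "basis": "absolute", "direction": "at_least", "threshold": 85, "unit": "ug", "rule_class": "AI"},
    {"rule_id": "selenium", "label": "Selenium", "nutrient": "selenium_ug", "basis": "absolute", "direction": "at_least", "threshold": 20, "unit": "ug", "rule_class": "AI"}
  ]
}
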