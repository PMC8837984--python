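group_id	name	rating	typical_servings
fruit	Fruit	beneficial	1.50
avocado	Avocado	beneficial	0.125
beans_legumes	Beans and legumes	beneficial	0.205
green_vegetables	Green vegetables	beneficial	0.52
yellow_vegetables	Yellow vegetables	beneficial	0.345
tomato	Tomato	beneficial	0.525
other_vegetables	Other vegetables	beneficial	2.155
nuts_seeds	Nuts and seeds	beneficial	0.765
soy_products	Soy products	beneficial	0.28
whole_grains	Whole grains	beneficial	1.58
vegetable_oil	Vegetable oil	beneficial	1.465
fatty_fish	Fatty fish	beneficial	0.045
lean_fish	Lean fish	beneficial	0.73
poultry	Poultry	beneficial	1.235
beer	Beer	beneficial	0.385
wine	Wine	beneficial	0.17
liquor	Liquor	beneficial	0.14
coffee	Coffee	beneficial	1.145
tea	Tea	beneficial	0.59
lowfat_dairy	Low-fat milk/Cheese/Yogurt	beneficial	1.115
potatoes	Potatoes	neutral	0.36
refined_grains	Refined grains	neutral	4.375
margarine	Margarine	neutral	1.51
chocolate	Chocolate	neutral	0.17
meal_replacements	Meal replacements	neutral	0.01
pickled_foods	Pickled foods	neutral	0.345
sugar_substitutes	Sugar substitutes	neutral	0.07
lean_red_meats	Lean red meats	neutral	0.68
shellfish	Shellfish	neutral	0.20
eggs	Eggs	neutral	0.64
soups	Soups	neutral	0.03
diet_drinks	Diet soft drinks	neutral	0.395
fruit_juice	Fruit juice	neutral	1.84
fried_potatoes	Fried potatoes	adverse	0.34
grain_desserts	Grain desserts	adverse	0.72
salty_snacks	Salty snacks	adverse	0.035
pastries	Pastries	adverse	0.94
sweets	Sweets	adverse	1.465
highfat_red_meats	High-fat red meats	adverse	1.995
processed_meats	Processed meats	adverse	0.775
organ_meats	Organ meats	adverse	0.04
fried_poultry_fish	Fried poultry and fish	adverse	0.10
sauces	Sauces	adverse	4.655
soft_drinks	Soft drinks	adverse	1.555
wholefat_dairy	Whole-fat milk/Cheese/Yogurt	adverse	1.945
butter	Butter	adverse	4.605
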