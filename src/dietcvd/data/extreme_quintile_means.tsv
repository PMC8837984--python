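group_id	rating	apdqs_q1	apdqs_q5	keys_q1	keys_q5
fruit	beneficial	0.94	2.06	1.74	1.12
avocado	beneficial	0.01	0.24	0.10	0.06
beans_legumes	beneficial	0.17	0.24	0.22	0.17
green_vegetables	beneficial	0.13	0.91	0.57	0.28
yellow_vegetables	beneficial	0.08	0.61	0.41	0.18
tomato	beneficial	0.32	0.73	0.52	0.43
other_vegetables	beneficial	1.43	2.88	2.35	1.77
nuts_seeds	beneficial	0.40	1.13	1.03	0.56
soy_products	beneficial	0.09	0.47	0.25	0.22
whole_grains	beneficial	1.02	2.14	1.71	1.40
vegetable_oil	beneficial	0.89	2.04	1.52	1.43
fatty_fish	beneficial	0.01	0.08	0.03	0.03
lean_fish	beneficial	0.44	1.02	0.85	0.50
poultry	beneficial	1.06	1.41	1.24	1.11
beer	beneficial	0.30	0.47	0.50	0.37
wine	beneficial	0.04	0.30	0.19	0.13
liquor	beneficial	0.10	0.18	0.25	0.15
coffee	beneficial	0.45	1.84	1.00	1.34
tea	beneficial	0.33	0.85	0.74	0.38
lowfat_dairy	beneficial	0.57	1.66	1.08	1.17
potatoes	neutral	0.38	0.34	0.35	0.40
refined_grains	neutral	5.64	3.11	3.58	4.44
margarine	neutral	1.66	1.36	1.86	1.13
chocolate	neutral	0.22	0.12	0.14	0.21
meal_replacements	neutral	0.01	0.01	0.01	0.01
pickled_foods	neutral	0.29	0.40	0.32	0.33
sugar_substitutes	neutral	0.01	0.13	0.09	0.05
lean_red_meats	neutral	0.88	0.48	0.52	0.92
shellfish	neutral	0.13	0.27	0.20	0.20
eggs	neutral	0.79	0.49	0.29	1.08
soups	neutral	0.02	0.04	0.04	0.04
diet_drinks	neutral	0.11	0.68	0.52	0.29
fruit_juice	neutral	1.81	1.87	2.30	1.46
fried_potatoes	adverse	0.53	0.15	0.25	0.35
grain_desserts	adverse	0.98	0.46	0.52	0.67
salty_snacks	adverse	0.03	0.04	0.06	0.03
pastries	adverse	1.24	0.64	0.66	1.10
sweets	adverse	1.98	0.95	1.32	1.89
highfat_red_meats	adverse	2.86	1.13	1.48	2.54
processed_meats	adverse	1.21	0.34	0.52	1.02
organ_meats	adverse	0.06	0.02	0.03	0.06
fried_poultry_fish	adverse	0.14	0.06	0.09	0.12
sauces	adverse	4.61	4.70	4.57	4.30
soft_drinks	adverse	2.69	0.42	1.70	1.14
wholefat_dairy	adverse	2.53	1.36	0.89	3.29
butter	adverse	6.06	3.15	2.40	6.68
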