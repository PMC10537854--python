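nutrient,reference_type,age_min_months,age_max_months,value,units
energy,none,37,72,,kcal
carbohydrate,EAR,37,72,120,g
protein,EAR,37,72,25,g
fat,none,37,72,,g
calcium,EAR,37,72,650,mg
iron,EAR,37,72,7,mg
zinc,EAR,37,72,4.6,mg
iodine,EAR,37,72,65,ug
potassium,AI,37,72,1200,mg
vitamin_a,EAR,37,72,260,ug RAE
vitamin_b1,EAR,37,72,0.6,mg
vitamin_b2,EAR,37,72,0.6,mg
vitamin_b3,EAR,37,72,7,mg NE
vitamin_b6,EAR,37,72,0.5,mg
vitamin_b9,EAR,37,72,160,ug DFE
vitamin_b12,EAR,37,72,1.0,ug
vitamin_c,EAR,37,72,40,mg
vitamin_d,EAR,37,72,8,ug
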