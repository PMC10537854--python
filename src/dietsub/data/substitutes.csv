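food_id,name,category,form,reconstitution_factor,dairy_drink,energy_kcal,carbohydrate_g,protein_g,fat_g,calcium_mg,iron_mg,zinc_mg,iodine_ug,potassium_mg,vita_ug,vitb1_mg,vitb2_mg,vitb3_mgne,vitb6_mg,vitb9_ugdfe,vitb12_ug,vitc_mg,vitd_ug
soymilk,Soymilk,other,liquid,1.0,0,31,1.2,3,1.6,5,0.4,0.28,2.1,117,15,0.02,0.02,0.14,0.019,39.4,0.1,/,/
cow_milk,Cow's Milk,dairy_product,liquid,1.0,0,54,3.4,3,3.2,104,0.3,0.42,1.9,109,24,0.03,0.14,0.1,0.036,5,0.2,1,/
fmp_psc,FMP-PSC,dairy_product,powder,0.147,0,456.8,44.7,19.4,20.7,867,8.2,7.74,41.9,462,276,0.35,0.77,2.48,0.27,100,2.7,26.3,4.7
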