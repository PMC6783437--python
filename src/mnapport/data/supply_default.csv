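country,food_item,fw_supply_g,moisture_fraction
Tanzania,maize,163.6364,0.12
Tanzania,rice,30,0.12
Tanzania,beans,25,0.11
Tanzania,pigeon_peas,10,0.11
Tanzania,sukuma_wiki,45,0.90
Tanzania,pumpkin_leaves,15,0.90
Tanzania,spinach,10,0.90
Tanzania,tomato,35,0.94
Tanzania,onion,12,0.89
Tanzania,cassava,150,0.60
Tanzania,sweet_potato,50,0.70
Tanzania,banana,180,0.75
Tanzania,mango,25,0.83
Tanzania,sunflower_seeds,5,0.05
Kenya,maize,212.5,0.12
Kenya,rice,25,0.12
Kenya,beans,40,0.11
Kenya,sukuma_wiki,60,0.90
Kenya,pumpkin_leaves,10,0.90
Kenya,spinach,12,0.90
Kenya,tomato,40,0.94
Kenya,onion,12,0.89
Kenya,cassava,100,0.60
Kenya,sweet_potato,60,0.70
Kenya,banana,90,0.75
Kenya,mango,30,0.83
Kenya,sunflower_seeds,3,0.05
Kenya,groundnut,15,0.06
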