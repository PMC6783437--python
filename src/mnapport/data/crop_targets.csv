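country,food_item,food_group,Ca,Cu,Fe,Mg,Zn,Se,I,Mo
Tanzania,maize,maize,52,2.9,26,1188,17,0.14,0.004,0.4
Tanzania,rice,grain,243,2.9,146,1169,15,0.012,0.044,1.2
Tanzania,beans,pulses,1038,8.6,123,1879,32,0.143,0.008,2.8
Tanzania,pigeon_peas,pulses,1038,8.6,123,1879,32,0.143,0.008,9.15
Tanzania,sukuma_wiki,leafy_veg,29569,31.0,534,8985,54,0.094,0.242,2.1
Tanzania,pumpkin_leaves,leafy_veg,35614,47,1199,13259,54,0.094,0.310,2.1
Tanzania,spinach,leafy_veg,35614,31.0,600,8985,54,0.094,0.242,2.1
Tanzania,tomato,vegetables,6649,10,698,2723,36,0.071,0.635,1.7
Tanzania,onion,vegetables,6649,210,698,2723,36,0.071,0.635,1.7
Tanzania,cassava,root_tuber,259,6.6,19,1122,14,0.013,0.005,0.3
Tanzania,sweet_potato,root_tuber,259,58,19,1122,14,0.013,0.005,0.3
Tanzania,banana,fruit,1171,7.6,32,1585,18,0.062,0.007,0.2
Tanzania,mango,fruit,1171,7.6,32,1585,18,0.062,0.007,0.2
Tanzania,sunflower_seeds,seeds,1645,14.5,125,2891,38,0.303,0.014,0.3
Kenya,maize,maize,56,3.4,24,941,20,0.030,0.004,0.2
Kenya,rice,grain,510,12.2,105,1445,24,0.042,0.020,0.3
Kenya,beans,pulses,2151,15.0,141,2331,38,0.041,0.010,0.8
Kenya,sukuma_wiki,leafy_veg,24271,43.2,326,5489,49,0.055,0.087,0.8
Kenya,pumpkin_leaves,leafy_veg,14983,43.2,326,5489,49,0.055,0.087,0.8
Kenya,spinach,leafy_veg,14983,43.2,326,5489,49,0.055,0.087,0.8
Kenya,tomato,vegetables,3962,12,119,2714,31,0.030,0.004,0.4
Kenya,onion,vegetables,3962,81,119,2714,31,0.030,0.004,0.4
Kenya,cassava,root_tuber,1119,14.3,44,1380,18,0.021,0.010,0.1
Kenya,sweet_potato,root_tuber,1119,14.3,44,1380,18,0.021,0.010,0.1
Kenya,banana,fruit,1062,15.9,29,1579,17,0.017,0.007,0.2
Kenya,mango,fruit,1062,15.9,29,1579,17,0.017,0.007,0.2
Kenya,sunflower_seeds,seeds,1054,22.9,156,3665,56,0.059,0.004,0.9
Kenya,groundnut,nuts,592,23.9,54,2296,38,0.094,0.004,0.5
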