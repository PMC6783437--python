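country,source,n,pH,npoc_mg_L,conductivity_uS_cm,tds_mg_L,Ca_mg_L,Cu_ug_L,Fe_ug_L,Mg_mg_L,Zn_ug_L,Se_ug_L,I_ug_L,Mo_ug_L
Tanzania,piped,35,7.4,1.1,76,66,5.3,0.9,6.9,2.4,32,0.07,1.3,0.1
Tanzania,well,2,8.3,1.2,1200,740,8.1,0.2,1.4,3.6,1,1.98,35.4,14.9
Tanzania,rainwater,2,7.5,1.2,70,53,8.9,0.8,1.2,1.0,24,0.10,1.0,0.1
Tanzania,spring,1,6.3,0.3,67,49,2.4,0.2,1.0,1.3,4,0.05,5.5,0.1
Tanzania,borehole,1,7.6,2.7,817,598,64.5,1.2,1.0,32.6,41,0.05,49.7,1.0
Tanzania,surface,2,8.0,3.0,345,274,16.6,0.7,17.8,9.0,2,0.05,22.4,1.7
Kenya,piped,35,7.4,1.7,96,55,5.8,0.7,3.9,1.6,65,0.05,4.4,0.3
Kenya,well,64,7.2,0.9,112,77,6.2,0.4,8.1,1.8,7,0.07,3.5,0.1
Kenya,rainwater,29,6.7,1.5,34,25,2.1,0.6,4.9,0.3,282,0.08,1.8,0.1
Kenya,spring,58,7.3,0.8,100,56,6.1,0.3,4.2,2.1,8,0.07,2.0,0.1
Kenya,borehole,27,7.3,0.6,152,85,9.2,0.4,2.4,2.4,13,0.09,3.9,0.1
Kenya,surface,41,7.6,2.2,119,77,6.8,0.5,27.0,2.1,8,0.08,6.5,0.3
Kenya,undefined,3,7.9,1.1,296,175,23.7,0.4,8.9,8.8,21,0.13,5.3,0.3
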