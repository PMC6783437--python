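country,soil_class,pH,loi_percent,Ca,Cu,Fe,Mg,Zn,Se,I,Mo,Mn,Al,K,P,S
Tanzania,non_calcareous,5.8,9.4,7643,111,118845,4921,191,0.9,18.0,4.2,2000,90000,5500,1200,350
Tanzania,calcareous,7.0,5.6,18117,48,68098,6438,138,0.4,10.5,1.8,1500,70000,7000,1000,300
Kenya,non_calcareous,5.3,6.9,2777,19,45756,2006,110,0.6,10.0,3.1,1200,80000,4000,800,250
Kenya,calcareous,7.1,6.2,8269,24,52639,3506,128,0.4,5.7,2.1,1000,60000,5000,700,220
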