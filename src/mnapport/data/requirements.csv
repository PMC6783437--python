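element,sex,ear_mg_day,rni_mg_day,provenance,bioavailability_class,source
Ca,both,1200,,direct_ear,n/a,printed
Cu,both,0.7,,direct_ear,n/a,printed
Fe,F,90,,direct_ear,low,reconstructed
Fe,M,35.6,,direct_ear,low,reconstructed
Mg,F,260,,direct_ear,n/a,reconstructed
Mg,M,310,,direct_ear,n/a,reconstructed
Zn,F,11.7,,direct_ear,low,reconstructed
Zn,M,16.3,,direct_ear,low,reconstructed
Se,F,0.031,,direct_ear,n/a,reconstructed
Se,M,0.041,,direct_ear,n/a,reconstructed
I,both,0.150,,direct_ear,n/a,printed
Mo,both,0.034,,direct_ear,n/a,printed
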