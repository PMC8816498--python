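sample_id,size_nm,size_sd,pdi,pdi_sd,transmittance_pct,transmittance_sd,grade,formed
1,58.8,0.5,0.27,0.01,98.9,0.4,II,true
2,NA,NA,NA,NA,NA,NA,V,false
3,NA,NA,NA,NA,NA,NA,V,false
4,150.9,35.1,0.34,0.07,93.5,0.2,IV,true
5,NA,NA,NA,NA,NA,NA,V,false
6,140.1,41.6,0.20,0.03,99.0,0.1,II,true
7,169.2,2.3,0.28,0.02,86.2,0.4,IV,true
8,133.3,1.9,0.18,0.01,96.9,0.3,III,true
9,83.3,1.6,0.22,0.01,99.2,0.4,II,true
10,38.9,0.5,0.23,0.01,99.9,0.4,II,true
11,24.4,0.2,0.11,0.01,99.8,0.0,I,true
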