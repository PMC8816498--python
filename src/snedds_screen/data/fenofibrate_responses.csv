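sample_id,size_nm,size_sd,pdi,pdi_sd,transmittance_pct,transmittance_sd,grade,formed
1,137.5,0.7,0.16,0.01,97.1,0.0,III,true
2,34.2,0.2,0.29,0.00,99.8,0.2,I,true
3,119.7,1.3,0.20,0.01,98.1,0.2,III,true
4,175.6,1.4,0.30,0.00,77.4,0.3,IV,true
5,34.7,0.1,0.29,0.00,99.2,0.1,II,true
6,143.5,1.3,0.19,0.01,93.6,0.2,III,true
7,181.3,3.8,0.23,0.00,87.1,0.6,IV,true
8,18.6,0.3,0.06,0.01,99.9,0.1,I,true
9,96.3,0.6,0.24,0.01,99.1,0.2,II,true
10,114.6,1.2,0.17,0.01,99.1,0.2,III,true
11,86.9,0.7,0.19,0.00,99.6,0.1,II,true
12,107.4,1.4,0.21,0.01,98.8,0.1,III,true
13,156.3,1.5,0.18,0.01,94.6,0.3,III,true
14,161.0,2.7,0.17,0.01,92.7,0.7,III,true
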