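excipient,Miglyol 812,Brij 35,Tween 80,Gelucire 44/14,d-TPGS,Tetra EG
Miglyol 812,1,1,1,1,1,0
Brij 35,1,1,1,1,1,1
Tween 80,1,1,1,1,1,1
Gelucire 44/14,1,1,1,1,1,1
d-TPGS,1,1,1,1,1,1
Tetra EG,0,1,1,1,1,1
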