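drug,excipient,role,cs_mg_per_g
celecoxib,Miglyol 812,oil_lipid,7.0
celecoxib,Tween 80,surfactant,195.0
celecoxib,Gelucire 44/14,surfactant,162.0
celecoxib,d-TPGS,surfactant,155.43
fenofibrate,Miglyol 812,oil_lipid,30.0
fenofibrate,Brij 35,surfactant,120.0
fenofibrate,Tween 80,surfactant,150.0
fenofibrate,d-TPGS,surfactant,116.8
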