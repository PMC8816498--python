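drug,component,kind,mass_pct
celecoxib,Miglyol 812,excipient,30.27
celecoxib,Tween 80,excipient,49.85
celecoxib,Gelucire 44/14,excipient,4.55
celecoxib,d-TPGS,excipient,6.24
celecoxib,celecoxib,drug,9.09
fenofibrate,Miglyol 812,excipient,18.96
fenofibrate,Brij 35,excipient,9.48
fenofibrate,Tween 80,excipient,55.29
fenofibrate,d-TPGS,excipient,11.06
fenofibrate,fenofibrate,drug,5.21
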