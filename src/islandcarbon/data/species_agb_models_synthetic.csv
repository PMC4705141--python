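species,c0,c1,dbh_min,dbh_max
Metrosideros polymorpha,0.152,2.40,2.0,80.0
Acacia koa,0.090,2.52,2.0,90.0
Falcataria moluccana,0.060,2.55,2.0,100.0
Psidium cattleianum,0.210,2.30,1.0,30.0
Fraxinus uhdei,0.110,2.45,2.0,70.0
Eucalyptus robusta,0.085,2.50,2.0,110.0
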