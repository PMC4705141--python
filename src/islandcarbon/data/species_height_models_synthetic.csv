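species,c0,c1
Metrosideros polymorpha,1.90,0.62
Acacia koa,2.30,0.60
Falcataria moluccana,2.80,0.62
Psidium cattleianum,1.60,0.58
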