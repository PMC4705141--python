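level,name,density
species,Metrosideros polymorpha,0.69
species,Acacia koa,0.55
species,Falcataria moluccana,0.25
species,Psidium cattleianum,0.80
species,Fraxinus uhdei,0.45
species,Eucalyptus robusta,0.63
genus,Metrosideros,0.67
genus,Acacia,0.60
genus,Psidium,0.75
genus,Eucalyptus,0.60
genus,Cibotium,0.20
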