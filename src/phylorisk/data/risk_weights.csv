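category,iucn50,iucn500,edge2
LC,0.00005,0.0005,0.060625
NT,0.004,0.02,0.12125
VU,0.05,0.39,0.2425
EN,0.42,0.996,0.485
CR,0.97,1,0.97
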