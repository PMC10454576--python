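genotype,DW_shoot,RWC_leaf,ratio_K_Na_leaf,Na_leaf
G1,0.95,1.0,1.216,0.788
G2,0.648,0.852,0.726,1.367
G3,0.429,0.742,0.492,1.13
G4,0.834,0.905,1.372,1.069
G5,1.287,1.073,0.891,0.674
G6,1.088,0.992,1.286,1.136
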