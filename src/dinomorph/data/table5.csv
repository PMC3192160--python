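specimen,segment,model,mass_kg,mass_fraction,max_min_ratio
Carnegie,forelimb,all,13,0.002,
Sue,forelimb,all,11,0.001,
Stan,forelimb,all,21,0.004,
MOR,forelimb,all,18,0.003,
Jane,forelimb,all,18,0.028,
Carnegie,thigh,min,935,0.126,
Sue,thigh,min,1287,0.135,
Stan,thigh,min,1026,0.173,
MOR,thigh,min,1008,0.174,
Jane,thigh,min,99,0.155,
Carnegie,thigh,max,1452,0.100,1.55
Sue,thigh,max,2676,0.145,2.08
Stan,thigh,max,2286,0.211,2.23
MOR,thigh,max,2197,0.204,2.18
Jane,thigh,max,277,0.215,2.80
Carnegie,shank,min,410,0.055,
Sue,shank,min,407,0.043,
Stan,shank,min,342,0.058,
MOR,shank,min,326,0.056,
Jane,shank,min,38,0.059,
Carnegie,shank,max,835,0.057,2.04
Sue,shank,max,829,0.045,2.04
Stan,shank,max,766,0.071,2.24
MOR,shank,max,714,0.066,2.19
Jane,shank,max,110,0.087,2.92
Carnegie,foot,min,153,0.021,
Sue,foot,min,123,0.013,
Stan,foot,min,171,0.029,
MOR,foot,min,129,0.022,
Jane,foot,min,17,0.026,
Carnegie,foot,max,209,0.014,1.37
Sue,foot,max,196,0.011,1.59
Stan,foot,max,300,0.028,1.75
MOR,foot,max,222,0.021,1.72
Jane,foot,max,41,0.032,2.48
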