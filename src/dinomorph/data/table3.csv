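specimen,femur_length_m,body_length_m,gad_over_body_length,leg_length_m,tail_over_body_length,flag
Carnegie,1.265,11.88,0.212,3.040,0.470,tail_unusual
Sue,1.312,12.29,0.225,3.300,0.512,
Stan,1.278,11.78,0.211,3.068,0.594,
MOR,1.280,11.60,0.157,3.055,0.551,gad_unusual
Jane,0.788,6.452,0.178,2.125,0.599,
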