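specimen,segment,volume_m3,femur_tibiotarsus_ratio
Carnegie,femur,0.0430,0.98
Carnegie,tibiotarsus,0.0438,
Carnegie,tarsometatarsus,0.0176,
Sue,femur,0.0440,1.39
Sue,tibiotarsus,0.0316,
Sue,tarsometatarsus,0.0137,
Stan,femur,0.0340,1.43
Stan,tibiotarsus,0.0238,
Stan,tarsometatarsus,0.0140,
MOR,femur,0.0301,1.05
MOR,tibiotarsus,0.0288,
MOR,tarsometatarsus,0.0139,
Jane,femur,0.00600,1.39
Jane,tibiotarsus,0.00433,
Jane,tarsometatarsus,0.00156,
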