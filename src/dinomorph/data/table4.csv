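specimen,segment,model,mass_kg,mass_fraction,max_min_ratio
Carnegie,head,all,390,0.053,
Sue,head,all,392,0.041,
Stan,head,all,383,0.065,
MOR,head,all,640,0.111,
Jane,head,all,37,0.058,
Carnegie,neck,min,365,0.049,
Sue,neck,min,504,0.053,
Stan,neck,min,190,0.032,
MOR,neck,min,421,0.073,
Jane,neck,min,30,0.046,
Carnegie,neck,max,675,0.046,1.85
Sue,neck,max,737,0.040,1.46
Stan,neck,max,519,0.048,2.74
MOR,neck,max,1005,0.093,2.39
Jane,neck,max,75,0.058,2.53
Carnegie,body,min,4271,0.578,
Sue,body,min,5560,0.585,
Stan,body,min,3214,0.542,
MOR,body,min,2039,0.353,
Jane,body,min,327,0.512,
Carnegie,body,max,8606,0.591,2.01
Sue,body,max,10011,0.541,1.80
Stan,body,max,5269,0.486,1.64
MOR,body,max,3597,0.334,1.76
Jane,body,max,542,0.420,1.66
Carnegie,tail,min,858,0.116,
Sue,tail,min,1171,0.123,
Stan,tail,min,587,0.099,
MOR,tail,min,1196,0.207,
Jane,tail,min,74,0.115,
Carnegie,tail,max,2383,0.164,2.78
Sue,tail,max,3477,0.188,2.97
Stan,tail,max,1290,0.119,2.20
MOR,tail,max,2375,0.221,1.99
Jane,tail,max,168,0.130,2.28
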