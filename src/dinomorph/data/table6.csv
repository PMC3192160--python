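specimen,min_mass_kg,min_comx_m,min_comy_m,max_mass_kg,max_comx_m,max_comy_m,average_mass_kg,mass_range,erratum
Carnegie,7394,0.549,-0.332,14564,0.376,-0.347,9081,1.97,printed_average_not_mean_of_min_max
Sue,9502,0.801,-0.355,18489,0.572,-0.356,13996,1.95,
Stan,5934,0.524,-0.495,10837,0.504,-0.521,8385,1.83,
MOR,5777,0.572,-0.337,10768,0.386,-0.387,8272,1.86,
Jane,639,0.276,-0.318,1269,0.242,-0.307,954,1.98,
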