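specimen,model,body_mass_kg,comx_m,comy_m,comx_pct_femur,comy_pct_femur,comx_pct_body,comy_pct_body,comx_pct_gad,comy_pct_gad,comx_pct_leg,comy_pct_leg
Carnegie,most_cranial,11880,0.827,-0.275,65.4,-21.7,7.0,-2.3,33.2,-11.1,27.2,-9.0
Carnegie,most_caudal,10390,-0.024,-0.395,-1.90,-31.2,-0.20,-3.3,-1.00,-15.9,-0.8,-13.0
Carnegie,most_dorsal,13405,0.428,-0.300,33.8,-23.7,3.6,-2.5,17.2,-12.1,14.1,-9.9
Carnegie,most_ventral,8888,0.447,-0.388,35.3,-30.7,3.8,-3.3,18.0,-15.6,14.7,-12.8
Carnegie,maximal,14564,0.376,-0.347,29.7,-27.4,3.2,-2.9,15.1,-13.9,12.4,-11.4
Carnegie,minimal,7394,0.549,-0.332,43.4,-26.2,4.6,-2.8,22.1,-13.3,18.1,-10.9
Sue,most_cranial,14300,1.160,-0.361,91.2,-25.5,9.7,-2.7,43.2,-12.1,36.3,-10.2
Sue,most_caudal,13691,0.116,-0.350,13.6,-24.7,1.4,-2.6,6.40,-11.7,5.4,-9.8
Sue,most_dorsal,16605,0.641,-0.358,51.5,-25.4,5.5,-2.7,24.4,-12.0,20.5,-10.1
Sue,most_ventral,11386,0.662,-0.352,55.5,-24.8,5.9,-2.6,26.3,-11.7,22.1,-9.8
Sue,maximal,18489,0.572,-0.356,46.0,-24.9,4.9,-2.7,21.8,-11.8,18.3,-9.9
Sue,minimal,9502,0.801,-0.355,66.8,-25.5,7.1,-2.7,31.7,-12.1,26.6,-10.2
Stan,most_cranial,8319,0.869,-0.511,68.0,-40.0,7.4,-4.3,34.9,-20.6,28.3,-16.7
Stan,most_caudal,8450,0.154,-0.602,12.1,-47.1,1.3,-5.1,6.20,-24.2,5.0,-19.6
Stan,most_dorsal,9023,0.622,-0.488,48.6,-38.2,5.3,-4.1,25.0,-19.6,20.3,-15.9
Stan,most_ventral,7746,0.378,-0.637,29.5,-49.9,3.2,-5.4,15.2,-25.6,12.3,-20.8
Stan,maximal,10837,0.504,-0.521,39.4,-40.8,4.3,-4.4,20.3,-20.9,16.4,-17.0
Stan,minimal,5934,0.524,-0.495,41.0,-38.7,4.4,-4.2,21.1,-19.9,17.1,-16.1
MOR,most_cranial,7918,0.881,-0.279,68.8,-21.8,7.6,-2.4,48.3,-15.3,28.8,-9.1
MOR,most_caudal,8626,0.056,-0.453,4.40,-35.4,0.5,-3.9,3.1,-24.8,1.8,-14.8
MOR,most_dorsal,9098,0.511,-0.321,39.9,-25.1,4.4,-2.8,28.0,-17.6,16.7,-10.5
MOR,most_ventral,7447,0.378,-0.428,29.5,-33.5,3.3,-3.7,20.7,-23.5,12.4,-14.0
MOR,maximal,10768,0.386,-0.387,30.2,-30.2,3.3,-3.3,21.2,-21.2,12.6,-12.7
MOR,minimal,5777,0.572,-0.337,44.7,-26.3,4.9,-2.9,31.4,-18.5,18.7,-11.0
Jane,most_cranial,975,0.428,-0.286,54.4,-36.3,6.6,-4.4,37.3,-24.9,20.2,-13.5
Jane,most_caudal,1009,0.080,-0.397,10.2,-50.4,1.2,-6.2,7.0,-34.6,3.8,-18.7
Jane,most_dorsal,1069,0.298,-0.272,37.8,-34.5,4.6,-4.2,26.0,-23.7,14.0,-12.8
Jane,most_ventral,915,0.192,-0.423,24.4,-53.7,3.0,-6.6,16.8,-36.9,9.1,-19.9
Jane,maximal,1269,0.240,-0.294,30.5,-37.3,3.7,-4.6,20.9,-25.6,11.3,-13.8
Jane,minimal,639,0.276,-0.318,35.0,-40.3,4.3,-4.9,24.0,-27.7,13.0,-15.0
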