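specimen,cfl_min_kg,pct_body_min,cfl_max_kg,pct_body_max,erratum
Carnegie,187,2.53,520,3.57,
Sue,189,1.99,561,3.03,
Stan,192,3.24,22,3.90,printed_max_inconsistent_with_recipe
MOR,162,2.80,322,2.99,
Jane,34.0,5.32,77.4,6.10,
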