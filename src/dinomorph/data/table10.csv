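# Reference only: limb muscle and segment masses in extant amniotes, for
# comparison with the tyrannosaur extensor estimates.  No computation in this
# package consumes this table.
genus,body_mass_kg,clade,sampled_limb,extensor_pct_body,muscle_pct_body,limb_pct_body
Gecko,0.057,Squamata,pelvic,5.1,17,
Basiliscus,0.191,Squamata,pelvic,6.9,19,26
Iguana,4.04,Squamata,pelvic,2.5,6,15
Alligator,10,Crocodylia,pelvic,5.4,15,9.7
Coturnix,0.095,Aves,pelvic,5.5,11,
Pica,0.22,Aves,pelvic,2.8,7,18
Eudromia,0.406,Aves,pelvic,4.2,11,19
Numida,1.47,Aves,pelvic,9.1,23,27
Gallus,1.94,Aves,pelvic,6.6,16,
Meleagris,3.7,Aves,pelvic,5.5,12,20
Dromaius,27.2,Aves,pelvic,14.5,28,41
Struthio,65.3,Aves,pelvic,10.5,26,38
Lepus,3.45,Mammalia,pect+pelv,10.2,27,29
Macropus_rufus,6.6,Mammalia,pelvic,9.1,22,36
Macropus_rufogriseus,10.5,Mammalia,pelvic,9.6,22,
Canis,31.6,Mammalia,pect+pelv,12.5,36,33
Acinonyx,33.1,Mammalia,pect+pelv,11.2,32,40
Pan,54.6,Mammalia,pect+pelv,11.6,32,40
Homo,71,Mammalia,pelvic,9.5,9,39
Equus,510,Mammalia,pect+pelv,10.0,28,30
Giraffa,684.5,Mammalia,pect+pelv,11.3,32,
Hippopotamus,1600,Mammalia,pect+pelv,7.3,21,
Ceratotherium,1755,Mammalia,pect+pelv,6.8,20,
Elephas,3550,Mammalia,pect+pelv,6.7,20,27.7
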