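joint,model,Carnegie,Sue,Stan,MOR,Jane
hip,min,9.05,9.10,12.3,11.9,13.2
hip,max,8.79,10.7,15.1,13.9,17.6
knee,min,4.10,4.40,5.68,5.76,4.94
knee,max,3.29,4.80,7.07,6.84,7.27
ankle,min,2.33,1.90,2.52,2.42,2.46
ankle,max,2.55,2.00,3.22,2.99,3.93
total,min,15.5,15.4,20.5,20.1,20.6
total,max,14.6,17.6,25.4,23.7,28.8
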