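period,cycle,R1,R2,R3
3,1,0.630,0.185,0.185
3,2,0.185,0.630,0.185
3,3,0.185,0.185,0.630
6,1,0.630,0.185,0.185
6,2,0.482,0.482,0.036
6,3,0.185,0.630,0.185
6,4,0.036,0.482,0.482
6,5,0.185,0.185,0.630
6,6,0.482,0.036,0.482
12,1,0.630,0.185,0.185
12,2,0.590,0.333,0.076
12,3,0.482,0.482,0.036
12,4,0.333,0.590,0.076
12,5,0.185,0.630,0.185
12,6,0.076,0.590,0.333
12,7,0.036,0.482,0.482
12,8,0.076,0.333,0.590
12,9,0.185,0.185,0.630
12,10,0.333,0.076,0.590
12,11,0.482,0.036,0.482
12,12,0.590,0.076,0.333
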