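# title: Collimator scatter factor vs square field size, flattened beams, SCD 100 cm
# machine: Varian TrueBeam
field_size_cm,6MV_modeled,6MV_measured,10MV_modeled,10MV_measured
4,0.9709,0.9690,0.9739,0.9670
5,0.9778,0.9727,0.9802,0.9742
6,0.9836,0.9810,0.9854,0.9808
7,0.9885,0.9875,0.9898,0.9869
8,0.9928,0.9921,0.9936,0.9923
9,0.9966,0.9960,0.9970,0.9970
10,1.0000,1.0000,1.0000,1.0000
12,1.0059,1.0080,1.0053,1.0071
14,1.0110,1.0130,1.0098,1.0120
16,1.0154,1.0170,1.0137,1.0160
18,1.0193,1.0210,1.0171,1.0201
20,1.0227,1.0236,1.0202,1.0234
22,1.0259,1.0270,1.0230,1.0261
24,1.0288,1.0290,1.0256,1.0288
26,1.0315,1.0310,1.0280,1.0310
28,1.0340,1.0330,1.0302,1.0331
30,1.0363,1.0345,1.0322,1.0349
35,1.0415,1.0385,1.0368,1.0394
40,1.0460,1.0399,1.0408,1.0429
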