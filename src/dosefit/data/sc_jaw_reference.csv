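# title: Collimator scatter factor vs upper (rows) and lower (columns) jaw setting, 6 MV
# machine: Elekta Infinity
upper_cm,4,5,10,15,20,25,30,40
4,0.9511,0.9563,0.9671,0.9720,0.9739,0.9745,0.9751,0.9752
5,0.9587,0.9610,0.9773,0.9796,0.9801,0.9805,0.9814,0.9823
10,0.9730,0.9759,1.0000,1.0049,1.0063,1.0077,1.0086,1.0091
15,0.9798,0.9796,1.0104,1.0163,1.0181,1.0208,1.0222,1.0231
20,0.9856,0.9891,1.0167,1.0222,1.0258,1.0267,1.0289,1.0308
25,0.9872,0.9909,1.0204,1.0267,1.0285,1.0308,1.0326,1.0344
30,0.9903,0.9932,1.0231,1.0289,1.0331,1.0344,1.0376,1.0394
40,0.9952,0.9955,1.0285,1.0358,1.0381,1.0426,1.0449,1.0480
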