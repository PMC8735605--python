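# title: Fitted buildup-tail parameters per photon energy, 10x10 cm field
energy,n,mu
4 MV,0.17,0.0605
6 MV,0.208,0.0515
10 MV,0.495,0.0458
18 MV,1.2,0.0422
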