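population_a,population_b,fst,ldn
Luhya,Kikuyu,0.01,0.67
Kikuyu,Maasai,0.1,0.85
Luhya,Maasai,0.17,0.82
Maasai,Kalenjin,0.06,0.8
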