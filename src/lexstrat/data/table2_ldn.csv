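Luhya,Kikuyu,0.67
Kikuyu,Maasai,0.85
Luhya,Maasai,0.82
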