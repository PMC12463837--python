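Luhya,Kikuyu,0.01
Kikuyu,Maasai,0.1
Luhya,Maasai,0.17
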