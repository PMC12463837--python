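variety,family,water,fire,stone,eye,two,dog,sun,tree
alina,A,mawa,tiko,pema,liso,wili,mbwa,suba,miti
alumbe,A,mawe,tiko,pemba,riso,wili,mbua,suva,muti
akori,A,maua,tika,pema,liso,mili,mbwa,suba,mite
borchi,B,gola,dars,kutu,ila,lama,kere,adu,gaara
bashu,B,golba,dari,kutu,ilka,lama,keri,adu,gara
barendi,B,gola,daris,kuta,ila,lamma,kere,,gaar
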