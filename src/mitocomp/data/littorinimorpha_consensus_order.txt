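cox1,cox2,trnD,atp8,atp6,-trnM,-trnY,-trnC,-trnW,-trnQ,-trnG,-trnE,rrnS,trnV,rrnL,trnL1,trnL2,nad1,trnP,nad6,cytb,trnS2,-trnT,nad4l,nad4,trnH,nad5,trnF,cox3,trnK,trnA,trnR,trnN,trnI,nad3,trnS1,nad2
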