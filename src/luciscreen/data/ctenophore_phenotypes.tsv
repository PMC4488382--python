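species	luminous
Bfos	Y
Bchu	Y
Baby	Y
Bfor	Y
Binf	Y
Cfug	Y
Dgla	Y
Edun	Y
Hrub	Y
Hcal	N
Llac	Y
Lcru	Y
Mlei	Y
Omac	Y
Tinc	Y
spB	Y
spC	Y
spN1	Y
spN2	Y
spT	Y
spV	Y
spW	Y
Vpar	Y
Pbac	N
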