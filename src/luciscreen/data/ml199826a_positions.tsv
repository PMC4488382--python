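ref_id	position	residue	label
ML199826a	245	H	iron_his1
ML199826a	247	D	iron_asp
ML199826a	301	H	iron_his2
ML199826a	310	R	rxs_arg
ML199826a	312	S	rxs_ser
ML199826a	221	Y	acv_tyr
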