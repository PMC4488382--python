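	ML032920_35201	ML199826a	MLRB263543	MLRB263549	ML026010a	MLRB505111
ML032920_35201	=	-	-	-	-	-
ML199826a	100	=	-	-	-	-
MLRB263543	96	95	=	-	-	-
MLRB263549	97	97	98	=	-	-
ML026010a	48	46	45	47	=	-
MLRB505111	36	33	33	35	37	=
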