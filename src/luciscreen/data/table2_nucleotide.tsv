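	ML032920_35201	ML199826a	MLRB263543	MLRB263549	ML026010a	MLRB505111
ML032920_35201	=	-	-	-	-	-
ML199826a	97	=	-	-	-	-
MLRB263543	93	91	=	-	-	-
MLRB263549	94	94	97	=	-	-
ML026010a	54	52	53	56	=	-
MLRB505111	51	50	49	50	49	=
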