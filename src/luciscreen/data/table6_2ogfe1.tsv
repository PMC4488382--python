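	Cfug_2OGFe1	Edun_2OGFe1	spC_2OGFe1	spC_2OGFe1b	spB_2OGFe1	Bchu_2OGFe1	spW_2OGFe1	spN1_2OGFe1	Hcal_2OGFe1	Pbac_2OGFe1	Dgla_2OGFe1	Omac_2OGFe1	ML026010a	spV_2OGFe1	Lcru_2OGFe1	Tinc_2OGFe1	Bfor_2OGFe1	Hrub_2OGFe1
Cfug_2OGFe1	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Edun_2OGFe1	60	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spC_2OGFe1	53	51	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spC_2OGFe1b	53	51	100	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spB_2OGFe1	54	52	58	57	=	-	-	-	-	-	-	-	-	-	-	-	-	-
Bchu_2OGFe1	51	54	57	57	56	=	-	-	-	-	-	-	-	-	-	-	-	-
spW_2OGFe1	52	53	56	56	56	64	=	-	-	-	-	-	-	-	-	-	-	-
spN1_2OGFe1	53	55	58	58	56	65	84	=	-	-	-	-	-	-	-	-	-	-
Hcal_2OGFe1	49	50	50	50	54	51	55	53	=	-	-	-	-	-	-	-	-	-
Pbac_2OGFe1	44	46	47	47	48	51	50	51	63	=	-	-	-	-	-	-	-	-
Dgla_2OGFe1	57	55	58	58	59	60	63	65	61	57	=	-	-	-	-	-	-	-
Omac_2OGFe1	49	47	51	51	48	57	55	57	51	47	67	=	-	-	-	-	-	-
ML026010a	48	48	52	52	52	57	58	58	53	47	65	59	=	-	-	-	-	-
spV_2OGFe1	48	51	49	48	48	59	60	61	51	50	66	61	58	=	-	-	-	-
Lcru_2OGFe1	51	52	52	51	53	61	61	62	53	53	66	63	61	95	=	-	-	-
Tinc_2OGFe1	47	49	49	48	50	58	60	60	52	49	67	58	61	79	80	=	-	-
Bfor_2OGFe1	48	50	54	54	52	56	60	61	52	49	65	58	59	59	60	58	=	-
Hrub_2OGFe1	50	52	54	54	51	60	58	59	52	49	64	56	56	57	58	58	64	=
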