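	Edun_FYY1	Edun_FYY2	spB_FYY1	spC_FYY1	Bchu_FYY1	Llac_FYY1	spW_FYY1	spW_FYY2	spN1_FYY1	spN2_FYY1	Dgla_FYY1	Bfos_FYY1	spT_FYY1	spT_FYY2	spT_FYY3	Vpar_FYY1	Binf_FYY1	ML032920_35201	MLRB263543	ML199826a	Omac_FYY1	Tinc_FYY1	Tinc_FYY2	Lcru_FYY1	spV_FYY1	Baby_FYY1	Bfor_FYY1	Hrub_FYY1
Edun_FYY1	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Edun_FYY2	95	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spB_FYY1	66	66	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spC_FYY1	67	66	75	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Bchu_FYY1	65	65	71	70	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Llac_FYY1	71	71	74	74	71	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spW_FYY1	63	62	73	72	68	71	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spW_FYY2	65	64	75	72	69	73	89	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spN1_FYY1	65	65	74	70	69	74	85	91	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spN2_FYY1	66	65	74	70	69	74	85	91	98	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Dgla_FYY1	65	65	68	69	78	71	66	69	69	69	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Bfos_FYY1	65	65	67	69	71	70	69	69	70	69	69	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spT_FYY1	60	62	65	68	67	68	65	66	67	67	69	79	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spT_FYY2	61	62	64	68	67	69	66	66	67	67	68	79	99	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spT_FYY3	62	62	64	67	67	68	65	67	66	66	67	75	75	73	=	-	-	-	-	-	-	-	-	-	-	-	-	-
Vpar_FYY1	69	67	72	73	90	72	68	70	70	70	78	70	68	68	66	=	-	-	-	-	-	-	-	-	-	-	-	-
Binf_FYY1	66	64	70	72	91	71	68	70	69	69	79	70	67	67	66	94	=	-	-	-	-	-	-	-	-	-	-	-
ML032920_35201	71	69	73	77	89	73	72	73	71	71	82	73	70	70	71	93	93	=	-	-	-	-	-	-	-	-	-	-
MLRB263543	68	66	71	72	90	72	67	69	68	68	78	70	68	68	67	95	92	96	=	-	-	-	-	-	-	-	-	-
ML199826a	69	67	70	72	87	71	67	70	68	68	78	70	67	67	66	93	92	100	95	=	-	-	-	-	-	-	-	-
Omac_FYY1	64	63	68	70	88	67	66	66	65	64	74	68	66	66	66	84	84	89	85	83	=	-	-	-	-	-	-	-
Tinc_FYY1	68	68	74	74	71	75	73	76	74	73	70	69	66	66	68	72	73	75	72	71	69	=	-	-	-	-	-	-
Tinc_FYY2	65	64	75	72	70	75	86	96	90	90	69	71	67	68	68	70	71	73	70	70	67	76	=	-	-	-	-	-
Lcru_FYY1	66	66	74	73	70	74	70	72	73	72	68	71	70	70	68	71	70	71	70	70	68	80	73	=	-	-	-	-
spV_FYY1	66	66	74	73	68	73	71	72	73	72	67	70	70	70	66	71	69	71	70	69	68	79	72	95	=	-	-	-
Baby_FYY1	64	65	72	71	70	71	70	72	70	70	68	69	68	68	66	71	69	74	70	70	68	72	73	70	69	=	-	-
Bfor_FYY1	62	63	71	70	70	71	72	74	73	73	69	71	69	69	68	69	70	73	69	69	67	72	75	69	70	83	=	-
Hrub_FYY1	66	66	70	71	72	72	69	72	71	71	69	70	69	68	69	72	71	76	72	72	70	73	73	71	70	85	81	=
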