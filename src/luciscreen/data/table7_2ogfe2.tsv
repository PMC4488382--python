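	spC_2OGFe2	spB_2OGFe2	Llac_2OGFe2	Bchu_2OGFe2	spW_2OGFe2	spN2_2OGFe2	Bfos_2OGFe2	Hcal_2OGFe2	Pbac_2OGFe2	Dgla_2OGFe2	spT_2OGFe2	Binf_2OGFe2	Omac_2OGFe2	MLRB505111	spV_2OGFe2	Lcru_2OGFe2	Tinc_2OGFe2	Baby_2OGFe2
spC_2OGFe2	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spB_2OGFe2	63	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Llac_2OGFe2	79	65	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
Bchu_2OGFe2	67	64	68	=	-	-	-	-	-	-	-	-	-	-	-	-	-	-
spW_2OGFe2	65	58	63	68	=	-	-	-	-	-	-	-	-	-	-	-	-	-
spN2_2OGFe2	65	58	63	67	86	=	-	-	-	-	-	-	-	-	-	-	-	-
Bfos_2OGFe2	64	59	63	65	68	68	=	-	-	-	-	-	-	-	-	-	-	-
Hcal_2OGFe2	56	51	56	57	58	56	55	=	-	-	-	-	-	-	-	-	-	-
Pbac_2OGFe2	57	50	58	55	57	57	56	75	=	-	-	-	-	-	-	-	-	-
Dgla_2OGFe2	58	54	55	57	61	61	61	55	54	=	-	-	-	-	-	-	-	-
spT_2OGFe2	64	59	63	66	68	68	84	55	57	59	=	-	-	-	-	-	-	-
Binf_2OGFe2	65	60	63	67	65	66	69	57	57	63	67	=	-	-	-	-	-	-
Omac_2OGFe2	64	57	60	64	64	63	66	55	57	60	65	71	=	-	-	-	-	-
MLRB505111	63	59	63	68	67	66	68	59	59	61	68	71	69	=	-	-	-	-
spV_2OGFe2	57	53	57	61	62	62	63	50	50	56	63	66	64	64	=	-	-	-
Lcru_2OGFe2	57	54	56	60	63	62	63	50	50	55	62	67	64	64	97	=	-	-
Tinc_2OGFe2	64	60	64	68	66	65	70	57	56	63	69	72	68	73	74	74	=	-
Baby_2OGFe2	61	58	60	61	61	61	62	53	54	56	63	59	61	63	58	58	64	=
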