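Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-44	TRIM63	NM_032588	Het	Missense	Ex1:p.(Cys23Tyr)	rs754874432	31	LP/NA	0.00003182	MYBPC3:p.(Arg1022Pro); MYH7: p.(His1185Gln)
HCM-111	TRIM63	NM_032588	Hom	Missense	Ex1:p.(Cys23Tyr)	rs754874432	31	LP/NA	0.00003182	SVIL: p.(Ser1414Thr)
HCM-112	TRIM63	NM_032588	Hom	Missense	Ex2:p.(Cys75Tyr)	rs200811483	31	LP/Conflicting	0.00009952	Unique variant
HCM-113	TRIM63	NM_032588	Het	Missense	Ex2:p.(Cys75Tyr)	rs200811483	31	LP/Conflicting	0.00009952	Unique variant
HCM-63	TRIM63	NM_032588	Het	Missense	Ex2:p.(Cys75Tyr)	rs200811483	31	LP/Conflicting	0.00009952	MYH7: p.(Arg869His); MYLK2: p.(Ser510Leu)
HCM-114	TRIM63	NM_032588	Hom	Stopgain	Ex5:p.(Gln247*)	rs148395034	38	VUS/Conflicting	0.0006787	Unique variant
HCM-115	TRIM63	NM_032588	Het	Stopgain	Ex5:p.(Gln247*)	rs148395034	38	VUS/Conflicting	0.0006787	Unique variant
HCM-116	TRIM63	NM_032588	Het	Stopgain	Ex5:p.(Gln247*)	rs148395034	38	VUS/Conflicting	0.0006787	ACTN2: p.(Val458Met)
HCM-117	TRIM63	NM_032588	Het	Stopgain	Ex5:p.(Glu261*)	rs149312738	40	VUS/NA	0.00001416	Unique variant
HCM-118	TRIM63	NM_032588	Het	Missense	Ex5:p.(Glu269Lys)	rs61749355	26.4	LB/NA	0.003159	Unique variant
HCM-119	TRIM63	NM_032588	Het	Missense	Ex5:p.(Thr262Ile)	rs889710255	25.6	VUS/NA	0.000003982	SVIL: p.(Glu1286Lys)
HCM-120	TRIM63	NM_032588	Het	Missense	Ex7:p.(Ile322Thr)	rs368532655	23.6	VUS/VUS	0.00001989	SVIL: p.(Val1490Ala)
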