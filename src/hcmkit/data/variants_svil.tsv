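Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-129	SVIL	NM_021738	Het	Missense	Ex6:p.(Arg215Trp)	rs74132329	26.2	B/B	0.003420	Unique variant
HCM-108	SVIL	NM_021738	Het	Missense	Ex7:p.(Glu291Lys)	rs372012664	30	B/NA	0.00004242	FHOD3: p.(Arg638Trp)
HCM-130	SVIL	NM_021738	Het	Missense	Ex8:p.(Glu313Gly)	rs138539716	25.7	B/NA	0.004283	Unique variant
HCM-119	SVIL	NM_021738	Het	Missense	Ex21:p.(Glu1286Lys)	rs145704372	27.6	LB/NA	0.0003	TRIM63: p.(Thr262Ile)
HCM-111	SVIL	NM_021738	Het	Missense	Ex23:p.(Ser1414Thr)	rs144661370	29.6	B/LB	0.001681	TRIM63: p.(Cys23Tyr)
HCM-134	SVIL	NM_021738	Het	Missense	Ex23:p.(Ser1414Thr)	rs144661370	29.6	B/LB	0.001681	Unique variant
HCM-62	SVIL	NM_021738	Het	Missense	Ex23:p.(Ser1414Thr)	rs144661370	29.6	B/LB	0.001681	MYH7: p.(Gly768Arg)
HCM-120	SVIL	NM_021738	Het	Missense	Ex24:p.(Val1490Ala)	rs899379947	29.2	B/NA	0.00002477	TRIM63: p.(Ile322Thr)
HCM-39	SVIL	NM_021738	Het	Missense	Ex25:p.(Ala1496Asp)		32			MYBPC3: p.(Trp792ValfsTer41)
HCM-40	SVIL	NM_021738	Het	Missense	Ex27:p.(Thr1630Ser)	rs28451028	22.7	VUS/NA	0.004201	MYBPC3: p.(Ala833Val); MYH6: p.(Arg1532Leu)
HCM-82	SVIL	NM_021738	Het	Missense	Ex27:p.(Thr1630Ser)	rs28451028	22.7	VUS/NA	0.004201	CSRP3: p.(Trp4Arg)
HCM-138	SVIL	NM_021738	Het	Missense	Ex31:p.(Arg1870Gln)	rs762138005	35	VUS/NA	0.00001065	Unique variant
HCM-139	SVIL	NM_021738	Het	Missense	Ex33:p.(Lys1960Arg)		19		0.000003976	Unique variant
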