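Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-80	MYL2	NM_000432	Het	Missense	Ex5:p.(Gly92Ala)	NA	25.2	VUS/NA	NA	Unique variant
HCM-77	MYL3	NM_000258	Hom	Missense	Ex3:p.(Ala57Asp)	rs139794067	29.8	VUS/Conflicting	0.0001627	Unique variant
HCM-78	MYL3	NM_000258	Het	Missense	Ex3:p.(Arg94Cys)	rs730880961	33	VUS/VUS	0.00002388	Unique variant
HCM-79	MYL3	NM_000258	Het	Missense	Ex5:p.(Arg163Thr)	rs752165383	25.0	VUS/VUS	0.000003998	Unique variant
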