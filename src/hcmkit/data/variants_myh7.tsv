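Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-52	MYH7	NM_000257	Het	Missense	Ex8:p.(Asn232Ser)	NA	24.8	VUS/NA	NA	MYH6: p.(His1526Arg); CAV3: p.(Thr78Met)
HCM-53	MYH7	NM_000257	Het	Missense	Ex9:p.(Ile250Phe)	rs397516268	25.4	VUS/Conflicting	NA	Unique variant
HCM-54	MYH7	NM_000257	Het	Missense	Ex14:p.(Arg453Cys)	rs121913625	33	P/P	NA	Unique variant
HCM-55	MYH7	NM_000257	Het	Missense	Ex18:p.(Arg663His)	rs371898076	27.8	P/P	0.00001414	Unique variant
HCM-56	MYH7	NM_000257	Het	Missense	Ex19:p.(Arg694Cys)	rs727504240	34	VUS/Conflicting	0.00001989	Unique variant
HCM-57	MYH7	NM_000257	Het	Missense	Ex19:p.(Arg719Gln)	rs121913641	34	P/P	NA	SVIL: p.(Val1438Met)
HCM-58	MYH7	NM_000257	Het	Missense	Ex20:p.(Gly741Arg)	rs121913632	33	P/P	0.00003185	Unique variant
HCM-59	MYH7	NM_000257	Het	Missense	Ex20:p.(Ile736Thr)	rs727503261	24.7	P/P	NA	Unique variant
HCM-60	MYH7	NM_000257	Het	Missense	Ex21:p.(Ala797Thr)	rs3218716	20.5	P/P	0.00002386	Unique variant
HCM-61	MYH7	NM_000257	Het	Missense	Ex21:p.(Arg787Cys)	rs145677314	22.7	VUS/Conflicting	0.00006364	VCL: p.(His636Arg); MYPN: p.(Asp1208Gly)
HCM-62	MYH7	NM_000257	Het	Missense	Ex21:p.(Gly768Arg)	rs727503260	35	P/P	NA	SVIL: p.(Ser1414Thr)
HCM-63	MYH7	NM_000257	Het	Missense	Ex22:p.(Arg869His)	rs202141173	34	VUS/LP	0.00002386	MYLK2: p.(Ser510Leu); TRIM63: p.(Cys75Tyr)
HCM-44	MYH7	NM_000257	Het	Missense	Ex27:p.(His1185Gln)	NA	24.0	VUS/NA	NA	MYBPC3:p.(Arg1022Pro); TRIM63: p.(Cys23Tyr)
HCM-64	MYH7	NM_000257	Het	Missense	Ex33:p.(Glu1546Gly)	NA	29.3	VUS/NA	NA	Unique variant
HCM-65	MYH7	NM_000257	Het	Missense	Ex35:p.(Arg1712Gln)	rs193922390	28.3	LP/P	0.00002125	Unique variant
HCM-66	MYH7	NM_000257	Het	Missense	Ex37:p.(Glu1829Lys)	rs143562243	27.9	VUS/VUS	0.00001594	FLNC: p.(Arg1719Cys)
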