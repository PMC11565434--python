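Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-73	TNNT2	NM_001276345	Het	Missense	Ex9:p.(Val95Met)	NA	30	VUS/LP	NA	Unique variant
HCM-74	TNNT2	NM_001276345	Het	Missense	Ex16:p.(Lys283Glu)	rs1553279294	28.4	VUS/P	NA	Unique variant
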