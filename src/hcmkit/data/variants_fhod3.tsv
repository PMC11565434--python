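Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-103	FHOD3	NM_001281740	Het	Missense	Ex1:p.(Arg27Pro)	rs755501978	33	VUS/VUS	0.0001619	Unique variant
HCM-104	FHOD3	NM_001281740	Het	Missense	Ex6:p.(Leu177Phe)	rs781645381	26.8	VUS/NA	NA	Unique variant
HCM-105	FHOD3	NM_001281740	Het	Missense	Ex12:p.(Ser549Asn)	NA	21.1	NA	NA	Unique variant
HCM-106	FHOD3	NM_001281740	Het	Missense	Ex15:p.(Arg637Gln)	rs151313792	31	VUS/LB	0.001728	Unique variant
HCM-48	FHOD3	NM_001281740	Het	Missense	Ex15:p.(Arg637Gln)	rs151313792	31	VUS/LB	0.001728	MYBPC3: p.(Cys1202Leufs*35)
HCM-27	FHOD3	NM_001281740	Het	Missense	Ex15:p.(Arg637Gln)	rs151313792	31	VUS/LB	0.001728	MYBPC3: p.(Arg597Gln)
HCM-107	FHOD3	NM_001281740	Het	Missense	Ex15:p.(Arg637Gln)	rs151313792	31	VUS/LB	0.001728	Unique variant
HCM-108	FHOD3	NM_001281740	Het	Missense	Ex15:p.(Arg638Trp)	rs141148037	35	VUS/NA	0.0004252	SVIL: p.(Glu291Lys)
HCM-109	FHOD3	NM_001281740	Het	Missense	Ex17:p.(Glu687Lys)	rs778872098	24.8	VUS/NA	0.000007986	Unique variant
HCM-110	FHOD3	NM_001281740	Het	Missense	Ex28:p.(Val1570Ile)	rs201824593	33	VUS/NA	0.0007425	Unique variant
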