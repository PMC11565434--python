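Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-1	MYBPC3	NM_000256	Het	Splicing	Ex4:c.505 + 2 T > A	NA	23.5	LP/NA	NA	Unique variant
HCM-2	MYBPC3	NM_000256	Het	Stopgain	Ex4:p.(Ser139*)	rs730880704	35	LP/LP	NA	Unique variant
HCM-3	MYBPC3	NM_000256	Het	Missense	Ex5:p.(Arg177His)	rs201012766	23.5	B/B	0.001201	Unique variant
HCM-4	MYBPC3	NM_000256	Het	Stopgain	Ex5:p.(Gln205*)	rs397516061	36	LP/P	NA	Unique variant
HCM-5	MYBPC3	NM_000256	Het	Missense	Ex5:p.(Leu183Ile)	NA	24.3	VUS/NA	NA	MYBPC3:c.1928-2A > G
HCM-6	MYBPC3	NM_000256	Het	Missense	Ex5:p.(Ser217Gly)	rs138753870	14.62	B/Conflicting	0.001693	MYBPC3:p.(Arg943*)
HCM-7	MYBPC3	NM_000256	Het	Missense	Ex5:p.(Val189Ile)	rs11570052	20.0	B/B	0.002459	Unique variant
HCM-8	MYBPC3	NM_000256	Het	Missense	Ex5:p.(Val189Ile)	rs11570052	20.0	B/B	0.002459	Unique variant
HCM-9	MYBPC3	NM_000256	Het	Missense	Ex6:p.(Arg238Cys)	rs771143409	33	VUS/VUS	0.00001615	ACTN2: p.(Thr347Met)
HCM-10	MYBPC3	NM_000256	Het	Missense	Ex6:p.(Glu258Lys)	rs397516074	28.8	P/P	0.00002199	Unique variant
HCM-11	MYBPC3	NM_000256	Het	Missense	Ex8:p.(Arg281Gly)	rs371711564	23.4	VUS/VUS	NA	Unique variant
HCM-12	MYBPC3	NM_000256	Het	Frameshift deletion	Ex11:p.(Phe305ProfsTer27)	rs397516080	NA	LP/P	NA	Unique variant
HCM-13	MYBPC3	NM_000256	Het	Missense	Ex12:p.(Arg326Gln)	rs34580776	24.0	B/B	0.004359	Unique variant
HCM-14	MYBPC3	NM_000256	Het	Missense	Ex12:p.(Gly341Ser)	rs397515881	34	VUS/VUS	0.00004999	MYBPC3: p.(Pro955ArgfsTer95)
HCM-15	MYBPC3	NM_000256	Het	Missense	Ex12:p.(Val321Met)	rs200119454	26.5	VUS/Conflicting	0.0003297	Unique variant
HCM-16	MYBPC3	NM_000256	Het	Missense	Ex13:p.(Arg382Trp)	rs11570076	34	B/B	0.004239	Unique variant
HCM-17	MYBPC3	NM_000256	Het	Splicing	Ex14:c.1351 + 2 T > C	rs397515897	23.1	LP/P	NA	Unique variant
HCM-18	MYBPC3	NM_000256	Het	Frameshift deletion	Ex14:p.(Val437GlyfsTer13)	rs397515896	NA	LP/P	NA	Unique variant
HCM-19	MYBPC3	NM_000256	Het	Splicing	Ex16:c.1624 + 4A > T	rs397515916	NA	LP/P	0.00001334	Unique variant
HCM-20	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg495Gln)	rs200411226	30	LP/P	0.00002408	Unique variant
HCM-21	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg495Gln)	rs200411226	30	LP/P	0.00002408	Unique variant
HCM-22	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg495Gly)	rs397515905	25.4	P/P	0.000004013	Unique variant
HCM-23	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg502Trp)	rs375882485	34	P/P	0.00004632	Unique variant
HCM-24	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg502Trp)	rs375882485	34	P/P	0.00004632	Unique variant
HCM-25	MYBPC3	NM_000256	Het	Missense	Ex16:p.(Arg502Trp)	rs375882485	34	P/P	0.00004632	Unique variant
HCM-26	MYBPC3	NM_000256	Hom	Missense	Ex17:p.(Ala562Thr)	rs397515919	31	VUS/VUS	NA	Unique variant
HCM-27	MYBPC3	NM_000256	Het	Missense	Ex17:p.(Arg597Gln)	rs727503195	35	P/P	0.00002996	FHOD3: p.(Arg637Gln)
HCM-28	MYBPC3	NM_000256	Het	Missense	Ex18:p.(Glu611Lys)	rs730880555	35	VUS/Conflicting	0.00002350	Unique variant
HCM-29	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-30	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-31	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-32	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-5	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	MYBPC3: p.(Leu183Ile)
HCM-33	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-34	MYBPC3	NM_000256	Het	Splicing	Ex20:c.1928-2A > G	rs397515937	23.8	P/P	NA	Unique variant
HCM-35	MYBPC3	NM_000256	Het	Missense	Ex22:p.(Asp770Asn)	rs36211723	34	LP/Conflicting	0.00001606	Unique variant
HCM-36	MYBPC3	NM_000256	Het	Frameshift insertion	Ex22:p.(Lys754GlufsTer79)	rs774521272	NA	LP/P	0.000008025	Unique variant
HCM-37	MYBPC3	NM_000256	Het	Frameshift insertion	Ex22:p.(Lys754GlufsTer79)	rs774521272	NA	LP/P	0.000008025	Unique variant
HCM-38	MYBPC3	NM_000256	Het	Frameshift insertion	Ex23:p.(Trp792ValfsTer41)	rs397515963	NA	P/P	NA	Unique variant
HCM-39	MYBPC3	NM_000256	Het	Frameshift insertion	Ex23:p.(Trp792ValfsTer41)	rs397515963	NA	P/P	NA	SVIL: p.(Ala1496Asp)
HCM-40	MYBPC3	NM_000256	Het	Missense	Ex24:p.(Ala833Val)	rs3729952	26.9	B/B	0.002538	MYH6: p.(Arg1532Leu); SVIL: p.(Thr1630Ser)
HCM-41	MYBPC3	NM_000256	Het	Missense	Ex24:p.(Arg810His)	rs375675796	35	LP/Conflicting	0.00004816	Unique variant
HCM-6	MYBPC3	NM_000256	Het	Stopgain	Ex26:p.(Arg943*)	rs387907267	43	P/P	0.00001214	MYBPC3: p.(Ser217Gly)
HCM-42	MYBPC3	NM_000256	Het	Stopgain	Ex26:p.(Gln969*)	rs397515992	38	LP/P	NA	Unique variant
HCM-43	MYBPC3	NM_000256	Het	frameshift deletion	Ex26:p.(Pro955ArgfsTer95)	rs397515990	NA	P/P	0.00003187	Unique variant
HCM-14	MYBPC3	NM_000256	Het	frameshift deletion	Ex26:p.(Pro955ArgfsTer95)	rs397515990	NA	P/P	0.00003187	MYBPC3: p.(Gly341Ser)
HCM-44	MYBPC3	NM_000256	Het	Missense	Ex28:p.(Arg1022Pro)	rs397516000	34	VUS/Conflicting	0.00002517	MYH7: p.(His1185Gln); TRIM63: p.(Cys23Tyr)
HCM-45	MYBPC3	NM_000256	Het	Stopgain	Ex28:p.(Gln1061*)	rs397516005	39	LP/P	0.00001477	Unique variant
HCM-46	MYBPC3	NM_000256	Het	Missense	Ex30:p.(Arg1138His)	rs187705120	35	VUS/B	0.001139	Unique variant
HCM-47	MYBPC3	NM_000256	Het	Missense	Ex30:p.(Ile1131Thr)	rs370890951	22.5	B/Conflicting	0.0008403	Unique variant
HCM-48	MYBPC3	NM_000256	Het	Frameshift deletion	Ex31:p.(Cys1202Leufs*35)	NA	NA	NA	NA	FHOD3: p.(Arg637Gln)
HCM-49	MYBPC3	NM_000256	Het	stopgain	Ex32:p.(Cys1244*)	rs730880600	38	LP/P	NA	Unique variant
HCM-50	MYBPC3	NM_000256	Het	Stopgain	Ex32:p.(Cys1244*)	rs730880600	38	LP/P	NA	Unique variant
HCM-51	MYBPC3	NM_000256	Het	Missense	Ex32:p.(Ser1213Pro)	NA	25.3	VUS/NA	NA	Unique variant
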