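Patient ID	Gene	Transcript	Genotype	Variant type	AA change	rs ID	CADD	ACMG/ClinVar	GnomAD-AF	Additional variant
HCM-92	FLNC	NM_001458	Het	Missense	Ex4:p.(Ala280Thr)	rs778751919	34	VUS/VUS	0.00002004	Unique variant
HCM-93	FLNC	NM_001458	Het	Missense	Ex13:p.(Asp693Ala)	rs34972246	28.9	VUS/LB	0.003442	Unique variant
HCM-67	FLNC	NM_001458	Het	Missense	Ex23:p.(Arg1341Gln)	rs149641783	27.5	VUS/Conflicting	0.0009425	MYH6: p.(Gln277His)
HCM-94	FLNC	NM_001458	Het	Missense	Ex28:p.(Ala1588Gly)	rs148545460	27.5	VUS/Conflicting	0.0001603	Unique variant
HCM-95	FLNC	NM_001458	Het	Missense	Ex28:p.(Ser1624Leu)	rs879255639	34	VUS/Conflicting	0.00003189	Unique variant
HCM-66	FLNC	NM_001458	Het	Missense	Ex30:p.(Arg1719Cys)	rs773260834	34	VUS/VUS	0.000008022	MYH7: p.(Glu1829Lys)
HCM-96	FLNC	NM_001458	Het	Missense	Ex34:p.(Arg1860Cys)	rs181067717	34	VUS/LB	0.005209	Unique variant
HCM-97	FLNC	NM_001458	Het	Missense	Ex38:p.(Gly2106Val)	NA	28.6	NA	NA	Unique variant
HCM-98	FLNC	NM_001458	Het	Missense	Ex38:p.(Tyr2108Asn)	NA	28.6	NA	NA	Unique variant
HCM-99	FLNC	NM_001458	Het	Missense	Ex40:p.(Gly2199Arg)	rs368977589	23.3	VUS/Conflicting	0.00003239	Unique variant
HCM-100	FLNC	NM_001458	Het	Missense	Ex42:p.(Arg2364His)	rs201672146	25.7	VUS/LB	0.001724	MYPN: p.(Pro1112Leu)
HCM-101	FLNC	NM_001458	Het	Missense	Ex42:p.(Arg2364His)	rs201672146	25.7	VUS/LB	0.001724	Unique variant
HCM-102	FLNC	NM_001458	Het	Missense	Ex47:p.(Lys2637Gln)	rs767794768	20.9	VUS/VUS	0.00006479	Unique variant
HCM-67	MYH6	NM_002471	Het	Missense	Ex10:p.(Gln277His)	rs140660481	21.9	VUS/Conflicting	0.0003677	FLNC: p.(Arg1341Gln)
HCM-68	MYH6	NM_002471	Het	Missense	Ex21:p.(Arg860His)	rs115845031	24.9	B/Conflicting	0.001778	Unique variant
HCM-69	MYH6	NM_002471	Het	Missense	Ex22:p.(Glu932Lys)	NA	34	VUS/NA	NA	Unique variant
HCM-70	MYH6	NM_002471	Het	Missense	Ex23:p.(Ala1004Ser)	rs143978652	22.9	LP/Conflicting	0.0009651	Unique variant
HCM-71	MYH6	NM_002471	Het	Missense	Ex28:p.(Glu1295Gln)	rs34935550	29.1	LB/B	0.003167	Unique variant
HCM-72	MYH6	NM_002471	Het	Missense	Ex28:p.(Glu1295Gln)	rs34935550	29.1	LB/B	0.003167	Unique variant
HCM-40	MYH6	NM_002471	Het	Missense	Ex32:p.(Arg1532Leu)	rs34330111	34	VUS/Conflicting	0.0002794	MYBPC3: p.(Ala833Val); SVIL: p.(Thr1630Ser)
HCM-52	MYH6	NM_002471	Het	Missense	Ex32:p.(His1526Arg)	NA	25.5	NA	NA	MYH7: p.(Asn232Ser); CAV3: p.(Thr78Met)
HCM-124	MYPN	NM_032578	Het	Missense	Ex2:p.(Gln193Arg)	rs573684358	23.0	LB/VUS	0.0002188	Unique variant
HCM-100	MYPN	NM_032578	Het	Missense	Ex17:p.(Pro1112Leu)	rs71534278	27.3	VUS/VUS	0.003060	FLNC: p.(Arg2364His)
HCM-125	MYPN	NM_032578	Het	Missense	Ex17:p.(Pro1112Leu)	rs71534278	27.3	VUS/VUS	0.003060	Unique variant
HCM-126	MYPN	NM_032578	Het	Missense	Ex17:p.(Pro1112Leu)	rs71534278	27.3	VUS/VUS	0.003060	Unique variant
HCM-127	MYPN	NM_032578	Het	Missense	Ex17:p.(Ala1141Thr)	rs150404143	27.7	B/B	0.001085	JPH2: p.(Phe221Leu)
HCM-61	MYPN	NM_032578	Het	Missense	Ex18:p.(Asp1208Gly)	NA	29.7	NA	NA	MYH7: p.(Arg787Cys); VCL: p.(His636Arg)
HCM-9	ACTN2	NM_001103	Het	Missense	Ex10:p.(Thr347Met)	rs727504590	33	B/Conflicting	0.0001343	MYBPC3: p.(Arg238Cys)
HCM-121	ACTN2	NM_001103	Het	Missense	Ex12:p.(Arg438Trp)	rs563171274	34	VUS/Conflicting	0.00001194	Unique variant
HCM-116	ACTN2	NM_001103	Het	Missense	Ex12:p.(Val458Met)	rs895000018	33	LB/LB	0.000003985	TRIM63: p.(Gln247*)
HCM-122	ACTN2	NM_001103	Het	Missense	Ex17:p.(Lys694Asn)	rs748034053	24.7	LB/Conflicting	0.00003182	Unique variant
HCM-123	ACTN2	NM_001103	Het	Missense	Ex21:p.(Arg851His)	rs201335965	34	B/Conflicting	0.00004601	Unique variant
HCM-86	ALPK3	NM_020778	Het	Missense	Ex5:p.(Tyr497Cys)	rs116077141	25.6	B/B	0.001299	Unique variant
HCM-87	ALPK3	NM_020778	Het	Missense	Ex7:p.(Arg1483Trp)	rs370816513	34	VUS/VUS	0.00002784	Unique variant
HCM-88	ALPK3	NM_020778	Het	Missense	Ex7:p.(Gly1522Asp)	NA	24.4	NA	NA	Unique variant
HCM-76	ALPK3	NM_020778	Het	Missense	Ex14:p.(Arg1907Gln)	rs116585466	32	VUS/VUS	0.0001469	MYLK2: p.(Gly89Asp)
HCM-81	CSRP3	NM_003476	Het	Missense	Ex3:p.(Trp4Arg)	rs45550635	26.3	B/Conflicting	0.002285	Unique variant
HCM-82	CSRP3	NM_003476	Het	Missense	Ex3:p.(Trp4Arg)	rs45550635	26.3	B/Conflicting	0.002285	SVIL: p.(Thr1630Ser)
HCM-83	CSRP3	NM_003476	Het	Missense	Ex3:p.(Phe30Leu)	NA	32	VUS/VUS	NA	Unique variant
HCM-84	CSRP3	NM_003476	Het	Missense	Ex5:p.(Arg100His)	rs138218523	24.9	B/Conflicting	0.001323	Unique variant
HCM-75	MYLK2	NM_033118	Het	Missense	Ex3:p.(Ala87Thr)	rs753089175	22.8	VUS/VUS	0.00003595	Unique variant
HCM-76	MYLK2	NM_033118	Het	Missense	Ex3:p.(Gly89Asp)	rs115398036	23	B/B	0.004242	ALPK3: p.(Arg1907Gln)
HCM-63	MYLK2	NM_033118	Het	Missense	Ex11:p.(Ser510Leu)	rs907738836	27.9	NA	NA	MYH7: p.(Arg869His); TRIM63: p.(Cys75Tyr)
HCM-89	NEXN	NM_144573	Het	Missense	Ex9:p.(Glu332Ala)	rs201763096	23.2	B/B	0.004068	Unique variant
HCM-90	NEXN	NM_144573	Het	Missense	Ex9:p.(Glu332Ala)	rs201763096	23.2	B/B	0.004068	Unique variant
HCM-52	CAV3	NM_033337	Het	Missense	Ex2:p.(Thr78Met)	rs72546668	23.7	NA	0.002667	MYH7: p.(Asn232Ser); MYH6: p.(His1526Arg)
HCM-91	CAV3	NM_033337	Het	Missense	Ex2:p.(Thr78Met)	rs72546668	23.7	NA	0.002667	VCL: p.(Arg285Cys)
HCM-91	VCL	NM_014000	Het	Missense	Ex7:p.(Arg285Cys)	rs757517552	34	VUS/VUS	0.00001591	CAV3: p.(Thr78Met)
HCM-61	VCL	NM_014000	Het	Missense	Ex14:p.(His636Arg)	rs71579374	23.9	VUS/Conflicting	0.001485	MYH7: p.(Arg787Cys); MYPN: p.(Asp1208Gly)
HCM-85	TCAP	NM_003673	Het	Missense	Ex2:p.(Met71Thr)	rs143465226	23	VUS/NA	0.00001669	Unique variant
HCM-127	JPH2	NM_020433	Het	Missense	Ex2:p.(Phe221Leu)	rs558770240	23.2	B/Conflicting	0.001931	MYPN: p.(Ala1141Thr)
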