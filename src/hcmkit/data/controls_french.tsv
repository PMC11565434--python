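Variant	Allele count	Number of homozygotes	Allele number	AF in control cohort	MAF highest population in gnomAD
TCAP: p.Met71Thr	2	0	1920	0.001	African/African American: 6.582e-5
ALPK3: p.Arg1483Trp	1	0	1920	5.2083e-4	European non-Finnish: 6.155e-5
VCL: p.His636Arg	1	0	1920	5.2083e-4	European Finnish: 0.0063
FLNC: p.Arg1860Cys	28	2	1920	0.0145	European non-Finnish: 0.0082
TRIM63: p.Glu269Lys	6	0	1920	0.0031	European non-Finnish: 0.0058
TRIM63: p.Ile322Thr	6	0	1920	0.0031	European non-Finnish: 4.397e-5
MYPN: p.Pro1112Leu	3	0	1920	0.0015	Ashkenazi Jewish: 0.0097
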