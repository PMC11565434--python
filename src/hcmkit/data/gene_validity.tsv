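Gene symbol	HCM validity	Inheritance
MYBPC3	definitive	AD
MYH7	definitive	AD
MYL2	definitive	AD
MYL3	definitive	AD
TNNT2	definitive	AD
MYLK2	disputed	AD
CSRP3	definitive	SD
CSRP3	moderate	AD
MYH6	limited	AD
ACTN2	definitive	AD
ALPK3	definitive	AR
VCL	disputed	AD
JPH2	moderate	AD
NEXN	limited	AD
MYPN	disputed	AD
TCAP	disputed	AD
FLNC	not_curated	NA
FHOD3	under_curation	NA
CAV3	not_curated	NA
TRIM63	moderate	AR
TRIM63	disputed	AD
SVIL	not_curated	NA
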