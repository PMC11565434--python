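Symbol	Tier	Mechanism	Inheritance	Provenance
MYBPC3	core_sarcomeric	haploinsufficiency	AD	omim_hcm,clingen,initial_panel
MYH7	core_sarcomeric	dominant_negative	AD	omim_hcm,clingen,initial_panel
TNNT2	core_sarcomeric	dominant_negative	AD	omim_hcm,clingen,initial_panel
TNNI3	core_sarcomeric	dominant_negative	AD	omim_hcm,clingen,initial_panel
TPM1	core_sarcomeric	dominant_negative	AD	omim_hcm,clingen,initial_panel
ACTC1	core_sarcomeric	dominant_negative	AD	omim_hcm,clingen,initial_panel
MYL2	core_sarcomeric	unknown	AD	omim_hcm,clingen,initial_panel
MYL3	core_sarcomeric	unknown	AD	omim_hcm,clingen,initial_panel
FLNC	minor	unknown	AD	omim_hcm,initial_panel
MYH6	minor	unknown	AD	omim_hcm,initial_panel
MYPN	minor	unknown	AD	omim_hcm,initial_panel
ACTN2	minor	unknown	AD	omim_hcm,clingen,initial_panel
ALPK3	minor	unknown	AR	omim_hcm,clingen,initial_panel
CSRP3	minor	unknown	AD	omim_hcm,clingen,initial_panel
MYLK2	minor	unknown	AD	omim_hcm,initial_panel
NEXN	minor	unknown	AD	omim_hcm,initial_panel
CAV3	minor	unknown	AD	omim_hcm,initial_panel
VCL	minor	unknown	AD	omim_hcm,initial_panel
TCAP	minor	unknown	AD	omim_hcm,initial_panel
JPH2	minor	unknown	AD	omim_hcm,clingen,initial_panel
TNNC1	minor	unknown	AD	omim_hcm,initial_panel
TRIM63	emerging	unknown	AR	clingen,literature
FHOD3	emerging	unknown	AD	literature
SVIL	emerging	unknown	AD	literature
TTN	excluded	unknown	AD	initial_panel
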