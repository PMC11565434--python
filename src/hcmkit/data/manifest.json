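{
  "controls_french.tsv": "ab981e0b19789ed64cd5aa917567436cd411dab8d8e20f5506ed3439edc9d905",
  "gene_validity.tsv": "e80ce18e5b11e600df96ccec59e7f0e0896f3998e6be20e91d32d9f77d1b29db",
  "panel.tsv": "202f9bcfc32ae0459e6cc382c09dbd4f27e4b5b0c17f570c8dd18cdcd3722b97",
  "variants_fhod3.tsv": "1cd20689724b7436738ab937a665082da4459ced9488b7f3cffff11315d9799b",
  "variants_minor.tsv": "2cff267a3117b6b3048c121aad50d80f1cfe962ae991616a39bc5e3a644ce282",
  "variants_mlc.tsv": "16c93ddad26a43e4aa3d58bcd7a2bc5096fec9f1fa55e1002088f5f0cd4151f7",
  "variants_mybpc3.tsv": "db969584eb17a2aacd0bd9e0466987560af6c1fab359c2fd240b61ad0ccbe914",
  "variants_myh7.tsv": "bd03ad38e02e5b998e7c0b9fc794e5593a97e7f9cdc8ce73cd4c6348a0427f6e",
  "variants_svil.tsv": "e2c1bbb328ae2f96c36a18a7f6b6defd13b5563f34e545d4d3195e4538570782",
  "variants_tnnt2.tsv": "4070ec5d80df120bf5befb1777eb44ed1f4a7268b64b7fb6800e3eb85dae17ba",
  "variants_trim63.tsv": "a86a1dbffd36d43af4e724e11cc51098fd8411bfb30d008c1e5800c710b9e49b"
}
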