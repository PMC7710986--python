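# Two-heme wild type: gated NO binding over the 10-160 uM series.
protein:
  preset: two_heme
assay:
  kind: NO_binding
  protein_conc_M: 2.5e-6
  ligand_conc_M: [1.0e-5, 2.0e-5, 4.0e-5, 8.0e-5, 1.6e-4]
  replicates: 1
instrument:
  kind: stopped_flow
  duration_s: 0.25
wavelength_nm: 424
seed: 3
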