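# Two-heme wild type: anaerobic nitrite reductase assay, 0.05-1 mM nitrite
# with excess dithionite keeping the heme reduced.
protein:
  preset: two_heme
assay:
  kind: NiR
  protein_conc_M: 2.5e-6
  ligand_conc_M: [5.0e-5, 1.0e-4, 2.5e-4, 5.0e-4, 1.0e-3]
  dithionite_conc_M: 5.0e-3
  replicates: 1
seed: 21
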