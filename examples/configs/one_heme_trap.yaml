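# One-heme wild type: dithionite-trap O2 dissociation, triplicate at
# three dithionite levels.  Run:
#   glbkin simulate --config examples/configs/one_heme_trap.yaml --out ds/
#   glbkin analyze ds/ --config examples/configs/one_heme_trap.yaml --out report.json
protein:
  preset: one_heme
assay:
  kind: O2_dissociation_trap
  protein_conc_M: 2.5e-6
  O2_conc_M: 1.25e-4
  dithionite_conc_M: [6.75e-3, 13.5e-3, 27.5e-3]
  replicates: 3
instrument:
  kind: scanning_spectrophotometer
  sampling_s: 0.2
  duration_s: 25.0
  noise_sd_au: 0.002
n_phases_expected: 1
k_on_floor_per_M_s: 5.0e+8
seed: 11
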