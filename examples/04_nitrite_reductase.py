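"""Nitrite reductase activity: second-order regression and pH dependence.

Deoxyferrous heme reduces nitrite to NO anaerobically; excess dithionite
re-reduces the ferric product so the net observable is deoxy -> nitrosyl
conversion at the nitrite turnover rate.  The pseudo-first-order k_obs is
linear in [NO2-]; its slope is the bimolecular NiR constant.  Because the
protonated species (HNO2, pKa 3.25) is the reactive one, the apparent
constant rises tenfold per pH unit going down from pH 7.
"""

import numpy as np

import glbkin as g

NITRITE = [0.05e-3, 0.1e-3, 0.25e-3, 0.5e-3, 1.0e-3]  # M
assay = g.AssayConditions(assay_kind="NiR", protein_conc=2.5e-6,
                          dithionite_conc=5e-3)

two_heme = g.two_heme()  # bulk constant 726 /M/s over two equivalent hemes
traces = g.generate_assay_dataset(two_heme, assay, ("ligand_conc", NITRITE),
                                  n_replicates=1, seed=21)
rep = g.analyze_nir_dataset(traces, per_molecule_sites=2)
print("two-heme protein, nitrite series 0.05-1 mM:")
for conc, k in sorted(rep.rates["kobs_by_conc"]):
    print(f"  [NO2-] = {conc * 1e3:>5.2f} mM   k_obs = {k:8.4f} /s")
print(f"  verdict: {rep.rates['independence_verdict'].value}")
print(f"  k_NiR = {rep.rates['k_NiR_per_M_s']:.0f} /M/s per molecule"
      f"  (generator 726; per heme {rep.rates['k_NiR_per_heme_per_M_s']:.0f})")
print(f"  fold vs sperm whale myoglobin: "
      f"{rep.rates['fold_vs_references']['sperm_whale_myoglobin']:.0f}x")

print("\npH dependence of the apparent constant (HNO2 is the substrate):")
for pH in (7.0, 6.0, 5.0):
    k_app = g.nitrite_second_order(726.0, pH)
    print(f"  pH {pH:.1f}: k_app = {k_app:8.0f} /M/s")
pHs = np.linspace(5, 7, 11)
slope = np.polyfit(pHs, np.log10([g.nitrite_second_order(726.0, p)
                                  for p in pHs]), 1)[0]
print(f"  d log10(k_app) / d pH = {slope:.3f}  (protonation-limited: -1)")

print("""
Reading the numbers: the fitted slope recovers the generating bimolecular
constant within a few percent, and the log-linear pH dependence with
slope -1 confirms nitrous acid as the active species in the model.""")
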