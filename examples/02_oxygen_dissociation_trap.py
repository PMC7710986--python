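"""Dithionite-trap O2 dissociation: simulate, fit, extrapolate k_off.

Oxyferrous protein is mixed with excess dithionite, which scavenges free
O2 (but not heme-bound O2), so the loss of the oxy complex runs at the O2
dissociation rate.  The fitted pseudo-first-order rate rises slightly
with dithionite (less O2 recapture) and a hyperbola fit extrapolates the
limiting k_off.  The one-heme protein gives a single phase; the two-heme
protein is biphasic (two non-equivalent hemes).
"""

import glbkin as g

DITHIONITE = [6.75e-3, 13.5e-3, 27.5e-3]  # M
assay = g.AssayConditions(assay_kind="O2_dissociation_trap",
                          protein_conc=2.5e-6, O2_conc=125e-6)

# --- one-heme protein: monophasic, generator k_off = 0.277 /s
one_heme = g.one_heme()
traces = g.generate_assay_dataset(
    one_heme, assay, ("dithionite_conc", DITHIONITE), n_replicates=3, seed=11,
    instrument=g.scanning_spectrophotometer(duration=25.0, sampling=0.2),
)
rep = g.analyze_trap_dataset(traces, n_phases_expected=1, k_on_floor=5e8)
ph = rep.rates["phases"][0]
print(f"one-heme protein ({len(traces)} traces):")
print(f"  k_off(O2) = {ph['k_off_per_s']:.4f} +- {ph['k_off_stderr_per_s']:.4f} /s"
      f"   (generator 0.277 /s)")
print(f"  minimum K = {ph['K_min_per_M_2sf']:.2g} /M,"
      f" maximum Kd = {ph['Kd_max_M_2sf'] * 1e9:.2f} nM")

# --- two-heme protein: biphasic, generators 0.319 / 0.190 /s, 60:40 split
two_heme = g.two_heme()
traces = g.generate_assay_dataset(
    two_heme, assay, ("dithionite_conc", DITHIONITE), n_replicates=3, seed=11,
    instrument=g.scanning_spectrophotometer(duration=30.0, sampling=0.05),
)
rep = g.analyze_trap_dataset(traces, n_phases_expected=2, k_on_floor=5e8)
print(f"\ntwo-heme protein ({len(traces)} traces, biphasic):")
for ph in rep.rates["phases"]:
    print(f"  {ph['phase']:>4s} phase: k_off = {ph['k_off_per_s']:.4f} /s,"
          f"  K >= {ph['K_min_per_M_2sf']:.2g} /M")

print("""
Reading the numbers: the recovered k_off values sit within a few percent
of the generating constants; the hyperbola's k_max is the dissociation
rate freed of O2-recapture bias, and pairing it with the k_on floor
yields the minimum affinity constants.""")
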