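"""Distal-His-gated NO binding and dead-time censoring.

For a hexacoordinate heme, an exogenous ligand can only bind after the
distal His vacates the sixth coordination site, so at saturating ligand
the observed binding rate equals the His dissociation rate k_-H and is
independent of ligand concentration.  Removing the distal His
(His -> Leu mutant) removes the gate: binding becomes direct and
bimolecular, here so fast that the stopped-flow dead time (1.2 ms)
swallows the whole transition and only a lower bound on the rate can be
reported (half-times under 3 ms are unobservable at 1.2 ms sampling).
"""

import numpy as np

import glbkin as g

NO_SERIES = [10e-6, 20e-6, 40e-6, 80e-6, 160e-6]  # M
assay = g.AssayConditions(assay_kind="NO_binding", protein_conc=2.5e-6)
instr = g.stopped_flow(duration=0.25)

two_heme = g.two_heme()  # gated; k_-H = 126 /s
traces = g.generate_assay_dataset(two_heme, assay, ("ligand_conc", NO_SERIES),
                                  n_replicates=1, seed=3, instrument=instr)
rep = g.analyze_binding_dataset(traces)
print("gated (wild-type) protein, NO series 10-160 uM:")
for conc, k in sorted(rep.rates["kobs_by_conc"]):
    print(f"  [NO] = {conc * 1e6:>5.0f} uM   k_obs = {k:7.2f} /s")
print(f"  verdict: {rep.rates['independence_verdict'].value}")
print(f"  k_NO = {rep.rates['k_gated_per_s']:.1f} /s"
      f"  (generating k_-H = 126 /s)")

mutant = g.no_distal_his(two_heme)
mut_traces = g.generate_assay_dataset(mutant, assay,
                                      ("ligand_conc", [20e-6]),
                                      n_replicates=3, seed=5,
                                      instrument=instr)
mut_rep = g.analyze_binding_dataset(mut_traces)
print(f"\npentacoordinate mutant at 20 uM NO:")
print(f"  censored traces: {mut_rep.rates['n_censored']} of "
      f"{mut_rep.rates['n_traces']}")
print(f"  k_NO > {mut_rep.rates['lower_bound_per_s']:.0f} /s"
      " (transition complete within the dead time)")

print("""
Reading the numbers: the wild-type k_obs is flat across a 16-fold NO
range and equals the His dissociation rate -- the signature of gating.
The mutant's binding is too fast to time-resolve, so the pipeline reports
the censored bound ln2 / 3 ms = 231 /s instead of a rate constant.""")
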