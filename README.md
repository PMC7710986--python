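# glbkin

Ligand-binding kinetics of hexacoordinate phytoglobins: mass-action
simulation of the four rapid-kinetics assays used to characterise one-
and two-heme plant globins, instrument-realistic synthetic stopped-flow /
flash-photolysis data, Soret-band spectral modelling and unmixing, and
the inference chain that turns absorbance time courses back into rate
constants, censored bounds, and O₂ affinity constants.

## Who this is for

Hemoprotein kineticists and modellers who want to (a) simulate what a
stopped-flow or laser-flash instrument would record for a globin with
given rate constants, (b) test fitting pipelines on data with known
ground truth, or (c) analyse time-course CSVs (their own or synthetic)
into dissociation/association/NiR/NOD constants.

## The model

A globin has one or two heme sites. Each hexacoordinate site carries a
distal histidine that competes with exogenous ligands for the sixth
coordination position, so ligand binding is **gated**:

    Hb(6c)  ⇌  Hb(5c)  →  Hb–L
       k₋H, k_H    k′·[L]

with the observed pseudo-first-order rate

    k_obs = k₋H · k′[L] / (k_H + k′[L])

which saturates at the His dissociation rate k₋H (concentration
independence) when k′[L] ≫ k_H. The four assays are small mass-action
reaction networks integrated with a stiff ODE solver (LSODA, rtol 1e-10,
atol 1e-14 M):

* **O₂ dissociation (dithionite trap)** — HbO₂ → Hb + O₂ (k_off), with
  excess dithionite scavenging free O₂; fitted rates vs [dithionite] are
  extrapolated through a hyperbola to the limiting k_off.
* **CO rebinding after flash photolysis** — photolysis as an instant
  initial-state transformation; O₂ binds first (k_on[O₂] ≫ k_CO[CO]) and
  is then displaced by CO at k_off.
* **NO binding** — the gated scheme above; pentacoordinate (His→Leu
  mutant) sites bind NO directly and faster than the 1.2 ms dead time.
* **NO dioxygenase (NOD)** — HbO₂ + NO → Hb³⁺ + NO₃⁻, then the
  low-affinity ferric–NO complex.
* **Nitrite reductase (NiR)** — Hb²⁺ + NO₂⁻ → Hb³⁺ + NO with the
  apparent constant scaled by the HNO₂ protonation fraction
  (pKa 3.25), ferric re-reduction by dithionite, and NO capture by the
  remaining deoxy hemes.

Species spectra are sums of Gaussian bands (Soret anchored at
150 mM⁻¹cm⁻¹); observables are Beer–Lambert projections filtered through
an instrument profile (dead time, fixed sampling, additive 0.002 AU
Gaussian noise). Inference uses variable-projection multi-exponential
fits with corrected-AIC phase-count selection, OLS second-order
regressions, gating classification, and half-time-based dead-time
censoring (half-times under 2.5 sampling intervals yield lower bounds,
ln 2 / 3 ms ≈ 231 s⁻¹ at 1.2 ms sampling).

## Worked example

```python
import glbkin as g

# gated NO binding for the two-heme protein over 10-160 uM NO
glb = g.two_heme()
assay = g.AssayConditions(assay_kind="NO_binding", protein_conc=2.5e-6)
traces = g.generate_assay_dataset(
    glb, assay, ("ligand_conc", [10e-6, 20e-6, 40e-6, 80e-6, 160e-6]),
    n_replicates=1, seed=3, instrument=g.stopped_flow(duration=0.25),
)
report = g.analyze_binding_dataset(traces)
print(report.rates["independence_verdict"].value)  # gated_independent
print(round(report.rates["k_gated_per_s"], 1))     # 125.9

# minimum O2 affinity from the k_on floor and a fitted k_off
aff = g.affinity_constants(5e8, 0.277)
print(f"{aff.K_2sf:.1e}")                          # 1.8e+09
```

The fitted k_obs is flat across a 16-fold NO range and equals the
distal-His dissociation rate (126 s⁻¹ generator): binding is
gate-limited, not bimolecular. The affinity constant 1.8×10⁹ M⁻¹
(Kd ≈ 0.55 nM) means the protein stays oxygenated except under severe
hypoxia.

The `examples/` scripts walk one capability each (affinities and
reference fold-changes, the dithionite trap, gated NO binding and
censoring, NiR regression and its pH dependence, second-derivative band
resolution and spectral unmixing); `examples/configs/` holds YAML
configurations for the command-line interface:

```bash
glbkin simulate --config examples/configs/one_heme_trap.yaml --out ds/
glbkin analyze ds/ --config examples/configs/one_heme_trap.yaml --out report.json
glbkin report report.json
```

## Layout

```
src/glbkin/
  kinetics.py    reaction schemes, ODE engine, closed-form rate laws
  synth.py       instrument profiles, noise, datasets, CSV formats
  spectra.py     basis spectra, quantitation, D2, unmixing
  inference.py   multi-exponential fits, regressions, censoring
  workflows.py   per-assay dataset -> report pipelines
  presets.py     the characterised one- and two-heme proteins
  config.py/cli.py  YAML configs and the glbkin command line
```
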