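"""Soret-band second derivatives and spectral-series unmixing.

Overlapping Soret bands (hexacoordinate low-spin deoxy at 423 nm vs
pentacoordinate high-spin at 435 nm) merge into one peak in a raw
spectrum; the 15-point Savitzky-Golay second derivative (D2) resolves
them as two minima.  Time-resolved spectra of an assay are decomposed
into species concentrations by non-negative least squares against the
basis spectra.
"""

import numpy as np

import glbkin as g
from glbkin.spectra import Band, BasisSpectrum, Spectrum, band_minima, default_grid
from glbkin.synth import _grid_for

# --- D2 band resolution
wl = default_grid()
mix = (0.6 * BasisSpectrum("6cLS", (Band(423, 12, 150e3),)).extinction(wl)
       + 0.4 * BasisSpectrum("5cHS", (Band(435, 12, 150e3),)).extinction(wl))
spec = Spectrum(wl, 2.5e-6 * mix)
y = spec.absorbance
raw_peaks = wl[1:-1][(y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])]
print(f"raw spectrum peak(s): {raw_peaks[(raw_peaks > 400) & (raw_peaks < 460)]}")
mins = band_minima(g.second_derivative(spec, window_points=15))
print(f"D2 minima: {mins} nm  (generating centres 423 and 435 nm)")

# --- unmixing a nitrite-reductase spectral series
two_heme = g.two_heme()
cond = g.AssayConditions(assay_kind="NiR", protein_conc=2.5e-6,
                         ligand_conc=1e-4, dithionite_conc=5e-3)
scheme = g.build_scheme(two_heme, cond)
instr = g.scanning_spectrophotometer(duration=60.0, sampling=1.0,
                                     dead_time=1.0)
traj = g.simulate(scheme, _grid_for(instr))
labels = sorted({lab for lab, _ in scheme.spectral_species.values()})
basis = g.make_basis(labels)
series = g.generate_spectrum_series(traj, basis, instr, seed=17)
res = g.unmix_series(series, basis)

print(f"\nunmixed species over {len(res.times)} spectra (1/s for 1 min):")
for i, lab in enumerate(res.species):
    c = res.concentrations[i]
    print(f"  {lab:12s}  start {c[0] * 1e6:6.2f} uM  ->  end {c[-1] * 1e6:6.2f} uM")
print(f"  worst relative residual: {res.residual.max():.2e}")
total = res.concentrations.sum(axis=0)
print(f"  recovered heme pool: {total.min() * 1e6:.2f}-{total.max() * 1e6:.2f} uM"
      f"  (true {2 * cond.protein_conc * 1e6:.1f} uM)")

print("""
Reading the numbers: D2 recovers both band centres within 1 nm although
the raw spectrum shows a single merged peak; unmixing tracks the
deoxy -> nitrosyl conversion and conserves the total heme pool to within
a fraction of a percent at 0.002 AU noise.""")
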