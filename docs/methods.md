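# Methods

## Scope and model structure

The package models the ligand-binding kinetics of one- and two-heme
hexacoordinate globins as small mass-action reaction networks, renders
them into instrument-realistic absorbance data, and infers the rate
constants back with the same fitting chain a stopped-flow laboratory
would use. Units are molar and seconds throughout; temperature is
recorded but not modelled (no Arrhenius scaling).

A protein is one or two `HemeSite`s. Sites of a two-heme protein own
independent copies of the heme-state chain and share the free-ligand
pools, so ligand depletion couples the sites exactly as in a cuvette.
Per-site `signal_weights` set each site's share of the observable
amplitude (the spectral difference between sites is not otherwise
modelled); they default to equal shares, and to 60:40 for the two-heme
preset, where the amplitude split of the biphasic dissociation data is
not otherwise constrained.

## Rate parameters

Measured constants (defaults of the presets):

| parameter | two-heme (fast/slow site) | one-heme | units |
|---|---|---|---|
| k_off(O₂) | 0.319 / 0.190 | 0.277 | s⁻¹ |
| k_on(CO) | 11.7e5 / 1.32e5 | 1.43e5 | M⁻¹s⁻¹ |
| k₋H (≈ gated k_NO) | 126 | 114 | s⁻¹ |
| k_NiR (pH 7) | 726 per molecule | 382 | M⁻¹s⁻¹ |

Unmeasured parameters, with the reasoning behind the defaults:

* **k_on(O₂) = 1e9 M⁻¹s⁻¹.** Only the floor 5e8 is experimentally
  fixed (rebinding completes within the 5 µs detector dead time); 1e9 is
  a round value above it. Affinity constants reported by the pipeline
  always use the 5e8 floor, so they are minima.
* **k′_on(NO) = 2e8 M⁻¹s⁻¹ and k_H = 10 s⁻¹.** These two are not
  separately identifiable from gated-binding data; what the data fix is
  (i) the pentacoordinate mutant's complete conversion within the 1.2 ms
  dead time at 20 µM NO, requiring k′ ≳ 1.3e8, and (ii) gated k_obs
  flat to within experimental scatter over 10–160 µM NO, requiring
  k_H ≲ 0.005·k′·L_min ≈ 10 s⁻¹. The defaults are the smallest round
  values satisfying both. **Known limitation:** with k_H < k₋H the
  model's internal deoxy 6c⇌5c equilibrium sits ~93% pentacoordinate,
  whereas the resting protein is observed hexacoordinate. The gating
  parameters are therefore *effective kinetic* constants, not an
  equilibrium model of the resting state; see "Initial states" below for
  how the package keeps the two views consistent.
* **k_NOD = 7e7 M⁻¹s⁻¹.** Only the bound >250 s⁻¹ at ≥5 µM NO is
  known (implying ≥ 5e7 M⁻¹s⁻¹); 7e7 places the 5 µM assay just inside
  the censored regime, which is the observed behaviour.
* **Ferric–NO complex: k_on 1e4 M⁻¹s⁻¹, k_off 1 s⁻¹.** Low-affinity
  complex needed only to reproduce the ferric → ferric-NO spectral
  sequence after NO dioxygenase turnover.
* **Dithionite trap: one bimolecular step O₂ + DT → ∅ at 5e7
  M⁻¹s⁻¹.** A stand-in for the dithionite radical chemistry. The value
  is chosen so that recapture of released O₂ by the accumulated
  pentacoordinate deoxy pool stays a <2% perturbation over 6.75–27.5 mM
  dithionite: the dissociation time courses then remain clean mono- or
  biphasic exponentials, as observed, while k_obs still rises with
  dithionite and converges to k_off from below (the hyperbola the
  pipeline fits). A slower trap makes the escape fraction drift within
  a trace and visibly distorts two-exponential fits.
* **Ferric re-reduction in the NiR assay: 100 s⁻¹** (pseudo-first-order
  in excess dithionite). Must be fast enough that the ferric
  intermediate adds no lag to the deoxy turnover; at 10 s⁻¹ the fitted
  NiR slope comes out several percent low at 1 mM nitrite.
* **HNO₂ pKa 3.25** (25 °C standard value). The apparent NiR constant
  is k_NiR(pH 7) · f(pH)/f(7) with f = 1/(1+10^(pH−pKa)), giving the
  log-linear pH dependence with slope −1 far above the pKa.
* **NiR normalisation.** The two-heme bulk constant (726 M⁻¹s⁻¹) is
  treated per molecule by default and split over the two equivalent
  hemes for simulation (363 each), consistent with the one-heme
  protein's 382 under equal per-heme reactivity; `nir_per_molecule=False`
  selects the per-heme convention instead.

## Initial states

Prepared deoxyferrous protein starts fully hexacoordinate in every
assay — the resting form seen spectroscopically — rather than at the
model's internal gating equilibrium. In the NO-binding assay this
reproduces the full-amplitude gated phase the instrument records. In
the NiR assay the fresh 6c state relaxes to the model's mostly-5c
distribution within ~50 ms of mixing, long before the first scan; the
NiR instrument profile therefore carries a 1 s dead time and the default
observable is the 435 nm (5cHS) Soret, whose decay tracks the deoxy
pool. Flash photolysis is an instantaneous initial-state
transformation (`fraction_photolysed`, default 1.0).

## Numerics

LSODA with analytic Jacobian, rtol 1e-10, atol 1e-14 M, dense output
evaluated on the requested grid. The right-hand side uses integer
stoichiometry powers so it stays smooth through the tiny negative
excursions the error control explores; trajectories are verified
non-negative to tolerance and clipped at zero. Per-site heme
conservation is checked after every run (contract: ≤1e-8 relative at
default tolerances; observed drift is ~1e-11). Reported integration
accuracy against closed forms is ~1e-8 relative on the default path
(bounded by the solver's dense-output interpolation) and ~1e-10 with
Radau at rtol 1e-11.

Multi-exponential fits use variable projection: the optimiser works in
log-rates while amplitudes and baseline are solved linearly at each
step; five deterministic log-spaced rate seeds guard against local
minima. Phase count (0, 1, 2) is selected by corrected AIC, then two
identifiability guards demote doubtful phases: amplitude below 5% of
the total signal change, or rates within a factor 1.5 of each other.
Uncertainties come from the Gauss–Newton covariance at the optimum.
Fitting is unweighted least squares (noise is homoscedastic by
construction). The trap-saturation hyperbola and second-order
regressions use `scipy.optimize.curve_fit` and OLS; the gating verdict
requires both a 95% slope CI containing zero and a corrected-AIC
improvement of the linear over the constant model below 2.

Censoring: a trace is reported as a lower bound (never a rate) when
≥95% of the expected amplitude is gone at the first observable sample,
or when the empirical half-time — time from mixing, dead time included,
at which half the expected amplitude is gone — is below 2.5 sampling
intervals (3 ms at 1.2 ms sampling). The bound is ln 2 / 3 ms ≈
231 s⁻¹, deliberately not rounded. The empirical half-time is used
rather than a fitted rate because ligand depletion drags fitted rates
down within a trace, making a rate-threshold verdict noise-sensitive
exactly at the boundary.

## Synthetic data

The generator emulates: pseudo-first-order stopped-flow traces (1.2 ms
dead time and sampling, up to 2 s), laser-flash traces (5 µs dead
time), scanning-spectrophotometer series (0.2–1 s sampling; 1 s dead
time for NiR), additive homoscedastic Gaussian noise of 0.002 AU
(typical diode-array noise; no value is otherwise fixed), and spectra
built from Gaussian species bands at the catalogued centres with Soret
peak extinction anchored at 150 mM⁻¹cm⁻¹ (6cLS Soret FWHM 10 nm, 5cHS
14 nm, Q bands 14 nm at 0.1 relative amplitude). Ligated-state band
centres (oxyferrous 412, carboxy 419, ferrous-NO 417, ferric-NO 420 nm)
are generic b-type heme values, not measured for these proteins.
Per-trace seeds derive from the master seed by splitmix64 counter
hashing and are recorded in the trace metadata; identical seeds give
bit-identical datasets.

The two-heme trap assay is sampled at 0.05 s (600 points/trace):
separating a 1.68-fold rate pair at 0.002 AU noise is ill-conditioned
below ~600 points, and replicate rates are pooled by median per
concentration before the hyperbola for the same reason. The one-heme
assay uses 0.2 s sampling.

What passing tests do **not** show about real data: real traces carry
mixing artifacts, baseline drift, photobleaching and heteroscedastic
noise, none of which are modelled; real band shapes are not Gaussian
and extinction coefficients of non-ferric species are approximated by
the shared Soret anchor. Recovery rates measured here are therefore
upper bounds on what the same pipeline achieves on real instruments.

## Design choices that were genuinely open

* Observability bound reported as ln 2 / (2.5 sampling intervals), not
  rounded to 250 s⁻¹ (the two published statements of the limit differ
  by ~8%; the half-time form is the defensible one).
* The CO-displacement property (slow oxy→carboxy phase at k_off) holds
  only when free O₂ is scavenged during the slow phase; the
  flash-photolysis scheme therefore accepts dithionite in its
  conditions, and the property is exercised with the trap present.
* Whether the two hemes differ in k_on as well as k_off is not
  resolvable from these data; the presets differ per site only in
  k_off(O₂) and k_on(CO).
* Degenerate inputs: zero ligand gives k_obs = 0 (not an error); a
  saturated trap series (identical rates) returns k_max = that rate
  with c_half → 0; baseline-only traces select zero phases.

## Limitations

Geminate rebinding faster than the 5 µs detector limit, autoxidation,
temperature dependence, global multi-trace fitting, and Bayesian
uncertainty are out of scope. The gating constants are effective
values (see above); the resting 6c/5c equilibrium they imply is not the
observed one, which matters only if the package is used to predict
resting-state spectra from the kinetic parameters (use the spectra
module's species catalogue directly for that).
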