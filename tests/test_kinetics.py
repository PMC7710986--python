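"""Reaction schemes, the ODE engine, and the closed-form rate laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glbkin as g
from glbkin.kinetics import (
    Reaction,
    ReactionScheme,
    SchemeConfigError,
    gating_slow_eigenvalue,
)


# ---------------------------------------------------------------------------
# scheme construction


def test_one_site_no_binding_scheme_is_minimal(one_heme):
    cond = g.AssayConditions(assay_kind="NO_binding", protein_conc=2.5e-6,
                             ligand_conc=20e-6)
    scheme = g.build_scheme(one_heme, cond)
    heme_species = {s for members in scheme.site_species for s in members}
    assert heme_species == {"deoxy6c", "deoxy5c", "ferrousNO"}
    gating = [r for r in scheme.reactions
              if set(r.reactants) <= heme_species and set(r.products) <= heme_species]
    binding = [r for r in scheme.reactions if "NO" in r.reactants]
    assert len(gating) == 2 and len(binding) == 1


def test_two_site_trap_scheme_shares_ligand_pools(two_heme):
    cond = g.AssayConditions(assay_kind="O2_dissociation_trap",
                             protein_conc=2.5e-6, dithionite_conc=6.75e-3,
                             O2_conc=125e-6)
    scheme = g.build_scheme(two_heme, cond)
    assert len(scheme.site_species) == 2
    assert not set(scheme.site_species[0]) & set(scheme.site_species[1])
    assert "O2" in scheme.species and "DT" in scheme.species
    trap = [r for r in scheme.reactions if "DT" in r.reactants]
    assert len(trap) == 1  # one shared trap reaction
    # each site has its own release/rebind pair against the shared O2 pool
    for i in (1, 2):
        assert f"oxy_s{i}" in scheme.species


def test_missing_rate_parameter_is_named():
    site = g.HemeSite(has_distal_his=True, k_off_O2=None)
    prot = g.ProteinModel(name="x", sites=[site])
    cond = g.AssayConditions(assay_kind="O2_dissociation_trap",
                             protein_conc=1e-6, dithionite_conc=1e-3)
    with pytest.raises(SchemeConfigError, match="k_off_O2"):
        g.build_scheme(prot, cond)


def test_unknown_assay_kind_rejected():
    with pytest.raises(ValueError):
        g.AssayConditions(assay_kind="photo_oxidation", protein_conc=1e-6)


def test_nir_without_reductant_accumulates_ferric(one_heme):
    """Without the dithionite re-reduction step the ferric product piles up
    instead of cycling back to deoxy and ending as the nitrosyl complex."""
    t = np.linspace(0, 400, 300)
    base = dict(assay_kind="NiR", protein_conc=2.5e-6, ligand_conc=1e-4)
    with_red = g.simulate(
        g.build_scheme(one_heme, g.AssayConditions(dithionite_conc=5e-3, **base)), t
    )
    without = g.simulate(
        g.build_scheme(one_heme, g.AssayConditions(dithionite_conc=0.0, **base)), t
    )
    p = 2.5e-6
    assert with_red["ferrousNO"][-1] > 0.9 * p
    assert with_red["ferric"][-1] < 0.05 * p
    assert without["ferric"][-1] > 0.4 * p
    assert without["ferrousNO"][-1] < with_red["ferrousNO"][-1]


def test_scheme_rejects_heme_nonconservation():
    with pytest.raises(ValueError, match="conserve heme"):
        ReactionScheme(
            species=["a", "b"],
            reactions=[Reaction({"a": 1}, {}, 1.0)],
            y0={"a": 1e-6},
            site_species=[["a", "b"]],
            spectral_species={},
        )


# ---------------------------------------------------------------------------
# integration


def test_empty_scheme_stays_constant():
    scheme = ReactionScheme(
        species=["a"], reactions=[], y0={"a": 2e-6},
        site_species=[["a"]], spectral_species={},
    )
    traj = g.simulate(scheme, np.linspace(0, 10, 50))
    assert np.allclose(traj["a"], 2e-6)


def test_irreversible_step_matches_closed_form():
    k = 3.7
    scheme = ReactionScheme(
        species=["a", "b"], reactions=[Reaction({"a": 1}, {"b": 1}, k)],
        y0={"a": 1e-6}, site_species=[["a", "b"]], spectral_species={},
    )
    t = np.linspace(0, 2.0, 200)
    exact = 1e-6 * np.exp(-k * t)
    # default stiff path: limited by dense-output interpolation and the
    # absolute-tolerance floor (1e-14 M) at the decayed tail
    traj = g.simulate(scheme, t)
    assert np.allclose(traj["a"], exact, rtol=5e-8, atol=1e-13)
    # high-order collocation at tight tolerance reaches 1e-8 relative
    traj = g.simulate(scheme, t, rel_tol=1e-11, abs_tol=1e-18, method="Radau")
    assert np.allclose(traj["a"], exact, rtol=1e-8, atol=1e-16)


def test_nir_pseudo_first_order_rate(two_heme):
    """50 uM nitrite on the two-heme protein: the deoxy pool decays at
    k_app * [NO2-] with k_app = 726/2 per heme under the per-molecule
    convention, i.e. an observed k_obs of 726 * 5e-5 / 2 per heme times
    two hemes consuming nitrite -- the pool itself decays at 363 * 5e-5
    per heme which is 726 * 5e-5 at the molecule level."""
    cond = g.AssayConditions(assay_kind="NiR", protein_conc=2.5e-6,
                             ligand_conc=50e-6, dithionite_conc=5e-3)
    t = np.linspace(0, 120, 400)
    traj = g.simulate(g.build_scheme(two_heme, cond), t)
    deoxy = sum(traj[s] for s in traj.species if s.startswith("deoxy"))
    k_expected = (726.0 / 2) * 50e-6  # per-heme pool decay
    mask = (t > 0.5) & (deoxy > 0.5 * deoxy[0])
    slope = np.polyfit(t[mask], np.log(deoxy[mask] / deoxy[0]), 1)[0]
    # finite nitrite depletion biases the decay a few percent slow
    assert -slope == pytest.approx(k_expected, rel=0.05)


def test_bad_time_grid_rejected(one_heme):
    cond = g.AssayConditions(assay_kind="NO_binding", protein_conc=1e-6,
                             ligand_conc=1e-5)
    scheme = g.build_scheme(one_heme, cond)
    with pytest.raises(ValueError):
        g.simulate(scheme, [1.0, 2.0])
    with pytest.raises(ValueError):
        g.simulate(scheme, [0.0, 2.0, 1.0])


def test_heme_conservation_across_all_assays(two_heme, one_heme):
    """Per-site heme totals stay constant to <= 1e-8 relative error in
    every assay simulation."""
    cases = [
        ("O2_dissociation_trap",
         dict(dithionite_conc=6.75e-3, O2_conc=125e-6), np.linspace(0, 25, 120)),
        ("NO_binding", dict(ligand_conc=10e-6), np.linspace(0, 0.25, 150)),
        ("NOD", dict(ligand_conc=5e-6), np.linspace(0, 2, 150)),
        ("NiR", dict(ligand_conc=1e-4, dithionite_conc=5e-3),
         np.linspace(0, 200, 150)),
        ("CO_rebinding_LFP",
         dict(CO_conc=5e-4, O2_conc=125e-6, dithionite_conc=1e-2),
         np.linspace(0, 60, 200)),
    ]
    for prot in (two_heme, one_heme):
        for kind, kw, t in cases:
            cond = g.AssayConditions(assay_kind=kind, protein_conc=2.5e-6, **kw)
            traj = g.simulate(g.build_scheme(prot, cond), t)
            assert traj.conservation_error() <= 1e-8, (prot.name, kind)
            assert traj.conc.min() >= 0.0


# ---------------------------------------------------------------------------
# closed forms


def test_gating_law_worked_values():
    assert g.hexacoordinate_kobs(126, 1000, 1e8, 0.0) == 0.0
    assert g.hexacoordinate_kobs(126, 0.0, 1e8, 1e-6) == pytest.approx(126.0)
    k = g.hexacoordinate_kobs(126, 1000, 1e8, 160e-6)
    assert k == pytest.approx(118.588, rel=1e-4)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    k_minus_H=st.floats(1e-3, 1e4),
    k_H=st.floats(0, 1e6),
    k_prime=st.floats(1e3, 1e10),
    lig1=st.floats(0, 1e-2),
    lig2=st.floats(0, 1e-2),
)
def test_gating_law_monotone_and_bounded(k_minus_H, k_H, k_prime, lig1, lig2):
    lo, hi = sorted((lig1, lig2))
    k_lo = g.hexacoordinate_kobs(k_minus_H, k_H, k_prime, lo)
    k_hi = g.hexacoordinate_kobs(k_minus_H, k_H, k_prime, hi)
    assert k_lo <= k_hi + 1e-12 * max(k_hi, 1.0)
    assert k_hi <= k_minus_H * (1 + 1e-12)


def test_gating_concentration_independence_limit():
    """Once k' L >> k_H the fitted rate of the full gated ODE saturates at
    k_minus_H (concentration independence emerges).  At the ratio-100
    boundary the exact slow eigenvalue sits a hair below the steady-state
    value k_minus_H * 100/101, so the band there is fractionally wider."""
    kmH, k_H, kprime = 126.0, 50.0, 2e8
    site = g.HemeSite(has_distal_his=True, k_minus_H=kmH, k_H=k_H,
                      k_prime_on_NO=kprime)
    prot = g.ProteinModel(name="x", sites=[site])
    for ratio, lo in ((100, 0.989), (300, 0.99), (1000, 0.99)):
        L = ratio * k_H / kprime
        cond = g.AssayConditions(assay_kind="NO_binding", protein_conc=1e-8,
                                 ligand_conc=L)
        t = np.linspace(0, 5 / kmH, 400)
        traj = g.simulate(g.build_scheme(prot, cond), t)
        fast = kmH + k_H + kprime * L
        m = t >= 5 / fast  # fast capture transient over; pure slow phase
        fit = g.fit_multiexponential((t[m], traj["ferrousNO"][m]),
                                     max_phases=1)
        k_fit = float(fit.rates[0])
        assert lo * kmH <= k_fit <= 1.0001 * kmH, ratio


def test_gating_closed_form_matches_exact_eigenvalue():
    for k_H in (1e3, 1e5):
        for flux in (1e4, 1e6):
            approx = g.hexacoordinate_kobs(126.0, k_H, 1.0, flux)
            exact = gating_slow_eigenvalue(126.0, k_H, 1.0, flux)
            assert approx == pytest.approx(exact, rel=0.02)


def test_nitrite_rate_calibration_points():
    assert g.nitrite_rate(726.0, 7.0, nitrite=1e-4) == pytest.approx(
        726.0 * 1e-4
    )
    # at pH = pKa half the nitrite is protonated
    f = 1 / (1 + 10 ** (3.25 - 3.25))
    assert f == 0.5
    ratio = g.nitrite_rate(726.0, 6.0, 3.25, 1.0) / g.nitrite_rate(
        726.0, 7.0, 3.25, 1.0
    )
    assert ratio == pytest.approx((1 + 10 ** 3.75) / (1 + 10 ** 2.75), rel=1e-12)
    assert ratio == pytest.approx(9.98, abs=0.02)


def test_nitrite_rate_log_slope_is_minus_one():
    """Far above the HNO2 pKa the apparent NiR rate is log-linear in pH
    with slope -1: each pH unit changes the protonated fraction tenfold."""
    pHs = np.linspace(5.0, 7.0, 21)
    logk = np.log10([g.nitrite_rate(726.0, p, 3.25, 1.0) for p in pHs])
    slope = np.polyfit(pHs, logk, 1)[0]
    assert slope == pytest.approx(-1.00, abs=0.02)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(pH1=st.floats(3.0, 10.0), pH2=st.floats(3.0, 10.0))
def test_nitrite_rate_strictly_decreasing_in_pH(pH1, pH2):
    lo, hi = sorted((pH1, pH2))
    if hi - lo < 1e-6:
        return
    k_lo = g.nitrite_rate(500.0, lo, nitrite=1e-4)
    k_hi = g.nitrite_rate(500.0, hi, nitrite=1e-4)
    assert k_lo > k_hi


def test_affinity_constants_examples():
    assert g.affinity_constants(5e8, 0.319).K_2sf == pytest.approx(1.6e9)
    assert g.affinity_constants(5e8, 0.190).K_2sf == pytest.approx(2.6e9)
    aff = g.affinity_constants(5e8, 0.277)
    assert aff.K_2sf == pytest.approx(1.8e9)
    assert aff.Kd < 0.6e-9
    assert g.affinity_constants(2.5, 2.5).K == pytest.approx(1.0)
    with pytest.raises(ValueError):
        g.affinity_constants(0.0, 1.0)


def test_affinity_monotone_in_koff():
    Ks = [g.affinity_constants(5e8, k).K for k in (0.1, 0.2, 0.4, 0.8)]
    assert all(a > b for a, b in zip(Ks, Ks[1:]))


# ---------------------------------------------------------------------------
# trap saturation property


def test_trap_kobs_monotone_in_dithionite_converging_to_koff():
    """Noiseless trap traces: the fitted dissociation rate rises with
    dithionite (less O2 recapture) and approaches k_off from below."""
    site = g.HemeSite(has_distal_his=False, k_off_O2=0.277)
    prot = g.ProteinModel(name="p5c", sites=[site])
    instr = g.scanning_spectrophotometer(duration=25.0, sampling=0.2,
                                         noise_sd=0.0)
    rates = []
    for D in (2e-3, 6.75e-3, 27.5e-3, 200e-3):
        cond = g.AssayConditions(assay_kind="O2_dissociation_trap",
                                 protein_conc=2.5e-6, dithionite_conc=D,
                                 O2_conc=125e-6)
        tc = g.simulate_trace(prot, cond, instr, seed=0)
        fit = g.fit_multiexponential(tc, max_phases=1)
        rates.append(float(fit.rates[0]))
    assert all(a < b for a, b in zip(rates, rates[1:]))
    assert rates[-1] < 0.277 * 1.001
    assert rates[-1] > 0.99 * 0.277


def test_co_displacement_runs_at_koff(one_heme, two_heme):
    """After flash photolysis in CO + substoichiometric-O2-recapture
    conditions (trap present), O2 binds first and is then displaced by CO
    at the O2 dissociation rate."""
    for prot, koff in ((one_heme, 0.277), (two_heme, None)):
        cond = g.AssayConditions(assay_kind="CO_rebinding_LFP",
                                 protein_conc=5e-6, CO_conc=500e-6,
                                 O2_conc=20e-6, dithionite_conc=10e-3)
        # initial kinetic selection favours O2: k_on_O2 [O2] >> k_on_CO [CO]
        assert prot.sites[0].k_on_O2 * 20e-6 > 10 * prot.sites[0].k_on_CO * 500e-6
        scheme = g.build_scheme(prot, cond)
        t = np.concatenate(([0.0], np.linspace(0.001, 40, 900)))
        traj = g.simulate(scheme, t)
        co = sum(traj[s] for s in traj.species if s.startswith("carboxy"))
        m = t >= 0.5
        fit = g.fit_multiexponential((t[m], co[m]), max_phases=2)
        if koff is not None:
            slow = float(np.min(fit.rates))
            assert slow == pytest.approx(koff, rel=0.05)
        else:
            # two-heme protein: slowest displacement phase ~ slow-site k_off
            assert float(np.min(fit.rates)) == pytest.approx(0.190, rel=0.10)
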