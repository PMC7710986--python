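"""Parameter presets for the characterised one- and two-heme globins.

``two_heme`` is the two-heme protein (two non-equivalent hemes: distinct O2
dissociation and CO association rates, shared His-gating and NiR
reactivity); ``one_heme`` the one-heme protein.  Measured rate constants are
set per heme where the experiments resolve them; unmeasured gating
parameters use the package defaults (see the methods note).
"""

from __future__ import annotations

from dataclasses import replace

from .kinetics import HemeSite, ProteinModel

__all__ = ["two_heme", "one_heme", "no_distal_his", "O2_KON_FLOOR"]

#: Minimum O2 association rate constant resolvable by the flash-photolysis
#: setup; the measured on-rates exceed it (M^-1 s^-1).
O2_KON_FLOOR = 5.0e8


def one_heme() -> ProteinModel:
    """One-heme wild type: k_off(O2) 0.277 s^-1, k_on(CO) 1.43e5,
    k_NO 114 s^-1 (gated), k_NiR 382 M^-1 s^-1."""
    site = HemeSite(
        has_distal_his=True,
        k_minus_H=114.0,
        k_off_O2=0.277,
        k_on_CO=1.43e5,
        k_NiR_pH7=382.0,
    )
    return ProteinModel(name="one-heme-wt", sites=[site], heme_equivalent=False)


def two_heme() -> ProteinModel:
    """Two-heme wild type: biphasic O2 dissociation (0.319 / 0.190 s^-1),
    CO on-rates 11.7e5 (fast) / 1.32e5 (slow), gated k_NO 126 s^-1,
    bulk k_NiR 726 M^-1 s^-1 (per molecule by default).

    The fast site carries 60% of the observable amplitude (the split is
    not resolved experimentally; see methods note)."""
    fast = HemeSite(
        has_distal_his=True,
        k_minus_H=126.0,
        k_off_O2=0.319,
        k_on_CO=11.7e5,
        k_NiR_pH7=726.0,
    )
    slow = replace(fast, k_off_O2=0.190, k_on_CO=1.32e5)
    return ProteinModel(
        name="two-heme-wt",
        sites=[fast, slow],
        heme_equivalent=False,
        signal_weights=(0.6, 0.4),
        nir_per_molecule=True,
    )


def no_distal_his(protein: ProteinModel, name: str | None = None) -> ProteinModel:
    """Distal-His-to-Leu mutant: every site pentacoordinate (no gating)."""
    sites = [replace(s, has_distal_his=False) for s in protein.sites]
    return ProteinModel(
        name=name or f"{protein.name}-HisMutant",
        sites=sites,
        heme_equivalent=protein.heme_equivalent,
        signal_weights=protein.signal_weights,
        nir_per_molecule=protein.nir_per_molecule,
    )
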