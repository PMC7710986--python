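"""Mass-action kinetics of globin ligand-binding assays.

This module defines the reaction schemes behind the four rapid-mixing /
flash-photolysis assays used to characterise hexacoordinate phytoglobins
(O2 dissociation under a dithionite trap, CO rebinding after laser flash
photolysis, gated NO binding, NO dioxygenase and nitrite reductase
turnover) and integrates them as stiff mass-action ODE systems.

Closed-form limits used to validate the simulations live here too:

* ``hexacoordinate_kobs`` -- the distal-His gating law
  ``k_obs = k_-H * k'L / (k_H + k'L)``, the observed pseudo-first-order
  rate of exogenous ligand binding to a hexacoordinate heme when binding
  is effectively irreversible.
* ``nitrite_rate`` -- the pH dependence of the nitrite-reductase rate,
  driven by the HNO2/NO2- protonation equilibrium.
* ``affinity_constants`` -- K = k_on / k_off and Kd = 1/K.

All internal units are molar and seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AssayKind",
    "HemeSite",
    "ProteinModel",
    "AssayConditions",
    "Reaction",
    "ReactionScheme",
    "Trajectory",
    "SchemeConfigError",
    "SimulationError",
    "build_scheme",
    "simulate",
    "hexacoordinate_kobs",
    "gating_slow_eigenvalue",
    "nitrite_rate",
    "nitrite_second_order",
    "affinity_constants",
    "Affinity",
    "round_sig",
    "K_TRAP",
    "K_FERRIC_REREDUCTION",
    "K_ON_FERRIC_NO",
    "K_OFF_FERRIC_NO",
    "HNO2_PKA",
]

# Auxiliary rate constants that are not protein properties.
#: Bimolecular scavenging of free O2 by dithionite (M^-1 s^-1).  One
#: effective step stands in for the dithionite radical chemistry; the value
#: keeps O2 recapture by the accumulated pentacoordinate deoxy protein a
#: small perturbation over 6.75-27.5 mM dithionite, as required by the
#: clean mono/biphasic dissociation time courses observed experimentally.
K_TRAP = 5.0e7
#: Pseudo-first-order re-reduction of ferric heme by excess dithionite
#: (s^-1) in the nitrite-reductase assay.  Must be fast enough that the
#: ferric intermediate adds no visible lag to the deoxy turnover (a 10 s^-1
#: step would bias the apparent constant several percent low at the
#: highest nitrite concentrations).
K_FERRIC_REREDUCTION = 100.0
#: Low-affinity ferric-NO complex formation/dissociation (M^-1 s^-1, s^-1).
K_ON_FERRIC_NO = 1.0e4
K_OFF_FERRIC_NO = 1.0
#: pKa of nitrous acid at 25 C.
HNO2_PKA = 3.25


class SchemeConfigError(ValueError):
    """Raised when a protein/assay combination is missing required rates."""


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries stiffness context."""


class AssayKind(str, Enum):
    O2_DISSOCIATION_TRAP = "O2_dissociation_trap"
    CO_REBINDING_LFP = "CO_rebinding_LFP"
    NO_BINDING = "NO_binding"
    NOD = "NOD"
    NIR = "NiR"


@dataclass
class HemeSite:
    """Per-heme rate parameters.

    ``k_minus_H``/``k_H`` are the distal-His dissociation and re-association
    rates of the hexacoordinate deoxyferrous state; they are ignored when
    ``has_distal_his`` is False (the site is then always pentacoordinate).
    Defaults are the one-heme wild-type values where the source experiments
    pin them down, and field-typical magnitudes elsewhere (see the methods
    note for the choice of ``k_H`` and ``k_prime_on_NO``).

    Fields set to ``None`` are treated as unconfigured: an assay that needs
    them raises :class:`SchemeConfigError` naming the parameter.
    """

    has_distal_his: bool = True
    k_minus_H: Optional[float] = 114.0        # s^-1
    k_H: Optional[float] = 10.0               # s^-1
    k_prime_on_NO: Optional[float] = 2.0e8    # M^-1 s^-1 (5c iron)
    k_on_O2: Optional[float] = 1.0e9          # M^-1 s^-1 (5c iron)
    k_off_O2: Optional[float] = 0.277         # s^-1
    k_on_CO: Optional[float] = 1.43e5         # M^-1 s^-1
    k_NOD: Optional[float] = 7.0e7            # M^-1 s^-1
    k_NiR_pH7: Optional[float] = 382.0        # M^-1 s^-1 (apparent, pH 7)

    def __post_init__(self) -> None:
        for name in (
            "k_minus_H", "k_H", "k_prime_on_NO", "k_on_O2", "k_off_O2",
            "k_on_CO", "k_NOD", "k_NiR_pH7",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def require(self, names: Sequence[str], assay: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise SchemeConfigError(
                    f"assay {assay!r} requires heme-site parameter {name!r}, "
                    "which is not configured"
                )


@dataclass
class ProteinModel:
    """A globin with one or two heme sites.

    ``signal_weights`` are the relative contributions of each site to the
    observed absorbance change (they must sum to 1); ``heme_equivalent``
    marks the two sites of a two-heme protein as sharing parameters.
    ``nir_per_molecule`` selects the normalisation of ``k_NiR_pH7``: if
    True (default) the printed constant is per molecule and is divided
    over the sites for simulation; if False it is per heme.
    """

    name: str
    sites: List[HemeSite]
    heme_equivalent: bool = False
    signal_weights: Optional[Tuple[float, ...]] = None
    nir_per_molecule: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.sites) <= 2:
            raise ValueError("a ProteinModel has 1 or 2 heme sites")
        if self.signal_weights is None:
            self.signal_weights = tuple(1.0 / len(self.sites) for _ in self.sites)
        self.signal_weights = tuple(float(w) for w in self.signal_weights)
        if len(self.signal_weights) != len(self.sites):
            raise ValueError("signal_weights must match number of sites")
        if any(w < 0 for w in self.signal_weights):
            raise ValueError("signal_weights must be non-negative")
        if abs(sum(self.signal_weights) - 1.0) > 1e-9:
            raise ValueError("signal_weights must sum to 1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class AssayConditions:
    """Concentrations and solution conditions of one assay.

    ``ligand_conc`` is the assay's principal exogenous ligand (NO for
    NO_binding and NOD, nitrite for NiR).  All concentrations are molar
    (post-mixing), pH is unitless, temperature in Celsius (metadata only;
    no Arrhenius scaling is modelled).
    """

    assay_kind: AssayKind
    protein_conc: float = 2.5e-6
    ligand_conc: float = 0.0
    dithionite_conc: float = 0.0
    CO_conc: float = 0.0
    O2_conc: float = 0.0
    pH: float = 7.0
    temperature: float = 25.0

    def __post_init__(self) -> None:
        self.assay_kind = AssayKind(self.assay_kind)
        for name in ("protein_conc", "ligand_conc", "dithionite_conc",
                     "CO_conc", "O2_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 3.0 <= self.pH <= 10.0:
            raise ValueError("pH must be within [3, 10]")


@dataclass(frozen=True)
class Reaction:
    """One mass-action step: reactants -> products at rate constant k."""

    reactants: Dict[str, int]
    products: Dict[str, int]
    k: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant must be >= 0")
        for stoich in (self.reactants, self.products):
            for sp, nu in stoich.items():
                if not (isinstance(nu, (int, np.integer)) and nu >= 0):
                    raise ValueError(
                        f"stoichiometry of {sp} must be a non-negative integer"
                    )


@dataclass
class ReactionScheme:
    """Species, reactions and initial state for one assay.

    ``site_species`` lists, per heme site, the scheme species that carry
    that site's heme (used for conservation checks and observables);
    ``spectral_species`` maps scheme species to ``(basis label, weight)``
    pairs for Beer-Lambert projection, where the weight is the site's
    signal contribution.
    """

    species: List[str]
    reactions: List[Reaction]
    y0: Dict[str, float]
    site_species: List[List[str]]
    spectral_species: Dict[str, Tuple[str, float]]
    assay_kind: Optional[AssayKind] = None

    def __post_init__(self) -> None:
        index = {s: i for i, s in enumerate(self.species)}
        if len(index) != len(self.species):
            raise ValueError("duplicate species labels")
        for rxn in self.reactions:
            for sp in list(rxn.reactants) + list(rxn.products):
                if sp not in index:
                    raise ValueError(f"reaction references unknown species {sp!r}")
        for sp in self.y0:
            if sp not in index:
                raise ValueError(f"initial state references unknown species {sp!r}")
        # structural heme conservation: every reaction must leave the total
        # heme of every site unchanged
        for i, members in enumerate(self.site_species):
            mem = set(members)
            for rxn in self.reactions:
                net = sum(rxn.products.get(s, 0) for s in mem) - sum(
                    rxn.reactants.get(s, 0) for s in mem
                )
                if net != 0:
                    raise ValueError(
                        f"reaction {rxn.label or rxn} does not conserve heme "
                        f"of site {i}"
                    )

    @property
    def index(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def initial_vector(self) -> np.ndarray:
        y0 = np.zeros(len(self.species))
        for sp, c in self.y0.items():
            y0[self.index[sp]] = c
        return y0


@dataclass
class Trajectory:
    """Per-species concentration time courses from :func:`simulate`."""

    times: np.ndarray
    species: List[str]
    conc: np.ndarray  # shape (n_species, n_times)
    scheme: Optional[ReactionScheme] = None

    def __getitem__(self, sp: str) -> np.ndarray:
        return self.conc[self.species.index(sp)]

    def site_total(self, site: int) -> np.ndarray:
        assert self.scheme is not None
        members = self.scheme.site_species[site]
        idx = [self.species.index(s) for s in members]
        return self.conc[idx].sum(axis=0)

    def conservation_error(self) -> float:
        """Worst relative drift of per-site heme totals over the grid."""
        assert self.scheme is not None
        worst = 0.0
        for i in range(len(self.scheme.site_species)):
            tot = self.site_total(i)
            ref = tot[0]
            if ref > 0:
                worst = max(worst, float(np.max(np.abs(tot - ref)) / ref))
        return worst


# ---------------------------------------------------------------------------
# closed forms


def hexacoordinate_kobs(
    k_minus_H: float, k_H: float, k_prime_on: float, ligand: float
) -> float:
    """Gated pseudo-first-order binding rate of a hexacoordinate heme.

    ``k_obs = k_-H * k'L / (k_H + k'L)``: exogenous ligand capture is
    limited by distal-His dissociation, saturating at ``k_-H`` when the
    ligand outcompetes His re-association.  Degenerate zero inputs give 0.
    """
    for name, v in (("k_minus_H", k_minus_H), ("k_H", k_H),
                    ("k_prime_on", k_prime_on), ("ligand", ligand)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    flux = k_prime_on * ligand
    denom = k_H + flux
    if flux == 0.0 or denom == 0.0:
        return 0.0
    return k_minus_H * flux / denom


def gating_slow_eigenvalue(
    k_minus_H: float, k_H: float, k_prime_on: float, ligand: float
) -> float:
    """Exact slow relaxation rate of the two-step gating scheme.

    For 6c -> 5c (k_-H), 5c -> 6c (k_H), 5c + L -> bound (k'L, irreversible)
    the observed slow rate is the smaller root of
    ``lambda^2 - (a+b+c) lambda + a c = 0`` with a=k_-H, b=k_H, c=k'L.
    Used as the independent oracle for the steady-state approximation.
    """
    a, b, c = k_minus_H, k_H, k_prime_on * ligand
    s = a + b + c
    disc = s * s - 4.0 * a * c
    if disc < 0:
        disc = 0.0
    return 0.5 * (s - math.sqrt(disc))


def nitrite_second_order(
    k_NiR_pH7: float, pH: float, pKa: float = HNO2_PKA
) -> float:
    """Apparent second-order NiR constant at the given pH (M^-1 s^-1).

    Nitrous acid (HNO2) is the reactive species, so the apparent constant
    scales with the protonated fraction ``f(pH) = 1/(1 + 10^(pH - pKa))``,
    calibrated to the measured constant at pH 7:
    ``k_app(pH) = k_NiR_pH7 * f(pH)/f(7)``.
    """
    f = 1.0 / (1.0 + 10.0 ** (pH - pKa))
    f7 = 1.0 / (1.0 + 10.0 ** (7.0 - pKa))
    return k_NiR_pH7 * f / f7


def nitrite_rate(
    k_NiR_pH7: float, pH: float, pKa: float = HNO2_PKA, nitrite: float = 0.0
) -> float:
    """Pseudo-first-order NiR rate ``k_app(pH) * [NO2-]`` (s^-1)."""
    if nitrite < 0:
        raise ValueError("nitrite must be >= 0")
    return nitrite_second_order(k_NiR_pH7, pH, pKa) * nitrite


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class Affinity:
    """Equilibrium affinity K = k_on/k_off (M^-1) and Kd = 1/K (M)."""

    K: float
    Kd: float
    K_2sf: float
    Kd_2sf: float


def affinity_constants(k_on: float, k_off: float) -> Affinity:
    """Affinity constants from association and dissociation rates.

    Returns full precision alongside 2-significant-figure values, the
    precision at which such constants are conventionally reported.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("k_on and k_off must be > 0")
    K = k_on / k_off
    return Affinity(K=K, Kd=1.0 / K, K_2sf=round_sig(K, 2), Kd_2sf=round_sig(1.0 / K, 2))


# ---------------------------------------------------------------------------
# scheme construction

def _site_tag(name: str, i: int, n_sites: int) -> str:
    return name if n_sites == 1 else f"{name}_s{i + 1}"


def build_scheme(
    protein: ProteinModel,
    cond: AssayConditions,
    fraction_photolysed: float = 1.0,
) -> ReactionScheme:
    """Assemble the mass-action scheme of one assay.

    Two-site proteins get an independent copy of the heme-state chain per
    site, sharing the free-ligand pools.  Initial deoxyferrous states are
    fully hexacoordinate when the site carries a distal His (the resting
    form seen spectroscopically).  For ``CO_REBINDING_LFP`` the laser flash
    is an instantaneous initial-state transformation: a fraction
    ``fraction_photolysed`` of the carboxy protein starts pentacoordinate.
    """
    kind = AssayKind(cond.assay_kind)
    n = protein.n_sites
    species: List[str] = []
    reactions: List[Reaction] = []
    y0: Dict[str, float] = {}
    site_species: List[List[str]] = []
    spectral: Dict[str, Tuple[str, float]] = {}

    def add_species(name: str, c0: float = 0.0) -> str:
        if name not in species:
            species.append(name)
            if c0:
                y0[name] = c0
        elif c0:
            y0[name] = y0.get(name, 0.0) + c0
        return name

    def add_gating(site: HemeSite, d6: str, d5: str) -> None:
        reactions.append(Reaction({d6: 1}, {d5: 1}, site.k_minus_H, f"{d6}->{d5}"))
        reactions.append(Reaction({d5: 1}, {d6: 1}, site.k_H, f"{d5}->{d6}"))

    per_site_protein = cond.protein_conc  # each site carries one heme

    if kind is AssayKind.O2_DISSOCIATION_TRAP:
        o2 = add_species("O2", cond.O2_conc)
        if cond.dithionite_conc > 0:
            dt = add_species("DT", cond.dithionite_conc)
            reactions.append(Reaction({o2: 1, dt: 1}, {}, K_TRAP, "O2+DT->0"))
        for i, site in enumerate(protein.sites):
            site.require(["k_off_O2", "k_on_O2"], kind.value)
            if site.has_distal_his:
                site.require(["k_minus_H", "k_H"], kind.value)
            oxy = add_species(_site_tag("oxy", i, n), per_site_protein)
            d5 = add_species(_site_tag("deoxy5c", i, n))
            members = [oxy, d5]
            reactions.append(Reaction({oxy: 1}, {d5: 1, o2: 1}, site.k_off_O2))
            reactions.append(Reaction({d5: 1, o2: 1}, {oxy: 1}, site.k_on_O2))
            w = protein.signal_weights[i]
            spectral[oxy] = ("oxyferrous", w)
            spectral[d5] = ("deoxy_5cHS", w)
            if site.has_distal_his:
                d6 = add_species(_site_tag("deoxy6c", i, n))
                add_gating(site, d6, d5)
                members.append(d6)
                spectral[d6] = ("deoxy_6cLS", w)
            site_species.append(members)

    elif kind is AssayKind.CO_REBINDING_LFP:
        if not 0.0 <= fraction_photolysed <= 1.0:
            raise ValueError("fraction_photolysed must be in [0, 1]")
        co = add_species("CO", cond.CO_conc)
        o2 = add_species("O2", cond.O2_conc)
        if cond.dithionite_conc > 0:
            dt = add_species("DT", cond.dithionite_conc)
            reactions.append(Reaction({o2: 1, dt: 1}, {}, K_TRAP, "O2+DT->0"))
        for i, site in enumerate(protein.sites):
            site.require(["k_on_CO", "k_on_O2", "k_off_O2"], kind.value)
            if site.has_distal_his:
                site.require(["k_minus_H", "k_H"], kind.value)
            d5 = add_species(
                _site_tag("deoxy5c", i, n), per_site_protein * fraction_photolysed
            )
            hbco = add_species(
                _site_tag("carboxy", i, n),
                per_site_protein * (1.0 - fraction_photolysed),
            )
            oxy = add_species(_site_tag("oxy", i, n))
            members = [d5, hbco, oxy]
            reactions.append(Reaction({d5: 1, co: 1}, {hbco: 1}, site.k_on_CO))
            reactions.append(Reaction({d5: 1, o2: 1}, {oxy: 1}, site.k_on_O2))
            reactions.append(Reaction({oxy: 1}, {d5: 1, o2: 1}, site.k_off_O2))
            w = protein.signal_weights[i]
            spectral[d5] = ("deoxy_5cHS", w)
            spectral[hbco] = ("carboxy", w)
            spectral[oxy] = ("oxyferrous", w)
            if site.has_distal_his:
                d6 = add_species(_site_tag("deoxy6c", i, n))
                add_gating(site, d6, d5)
                members.append(d6)
                spectral[d6] = ("deoxy_6cLS", w)
            site_species.append(members)

    elif kind is AssayKind.NO_BINDING:
        no = add_species("NO", cond.ligand_conc)
        for i, site in enumerate(protein.sites):
            site.require(["k_prime_on_NO"], kind.value)
            if site.has_distal_his:
                site.require(["k_minus_H", "k_H"], kind.value)
            d5 = add_species(
                _site_tag("deoxy5c", i, n),
                0.0 if site.has_distal_his else per_site_protein,
            )
            fno = add_species(_site_tag("ferrousNO", i, n))
            members = [d5, fno]
            reactions.append(Reaction({d5: 1, no: 1}, {fno: 1}, site.k_prime_on_NO))
            w = protein.signal_weights[i]
            spectral[d5] = ("deoxy_5cHS", w)
            spectral[fno] = ("ferrous_NO", w)
            if site.has_distal_his:
                d6 = add_species(_site_tag("deoxy6c", i, n), per_site_protein)
                add_gating(site, d6, d5)
                members.append(d6)
                spectral[d6] = ("deoxy_6cLS", w)
            site_species.append(members)

    elif kind is AssayKind.NOD:
        no = add_species("NO", cond.ligand_conc)
        no3 = add_species("NO3")
        for i, site in enumerate(protein.sites):
            site.require(["k_NOD"], kind.value)
            oxy = add_species(_site_tag("oxy", i, n), per_site_protein)
            met = add_species(_site_tag("ferric", i, n))
            metno = add_species(_site_tag("ferricNO", i, n))
            site_species.append([oxy, met, metno])
            reactions.append(
                Reaction({oxy: 1, no: 1}, {met: 1, no3: 1}, site.k_NOD)
            )
            reactions.append(Reaction({met: 1, no: 1}, {metno: 1}, K_ON_FERRIC_NO))
            reactions.append(Reaction({metno: 1}, {met: 1, no: 1}, K_OFF_FERRIC_NO))
            w = protein.signal_weights[i]
            spectral[oxy] = ("oxyferrous", w)
            spectral[met] = ("ferric_6cLS", w)
            spectral[metno] = ("ferric_NO", w)

    elif kind is AssayKind.NIR:
        no2 = add_species("NO2", cond.ligand_conc)
        no = add_species("NO")
        for i, site in enumerate(protein.sites):
            site.require(["k_NiR_pH7", "k_prime_on_NO"], kind.value)
            if site.has_distal_his:
                site.require(["k_minus_H", "k_H"], kind.value)
            k_site = nitrite_second_order(site.k_NiR_pH7, cond.pH)
            if protein.nir_per_molecule:
                k_site /= n
            d5 = add_species(
                _site_tag("deoxy5c", i, n),
                0.0 if site.has_distal_his else per_site_protein,
            )
            met = add_species(_site_tag("ferric", i, n))
            fno = add_species(_site_tag("ferrousNO", i, n))
            members = [d5, met, fno]
            reactions.append(Reaction({d5: 1, no2: 1}, {met: 1, no: 1}, k_site))
            reactions.append(Reaction({d5: 1, no: 1}, {fno: 1}, site.k_prime_on_NO))
            w = protein.signal_weights[i]
            spectral[d5] = ("deoxy_5cHS", w)
            spectral[met] = ("ferric_6cLS", w)
            spectral[fno] = ("ferrous_NO", w)
            if site.has_distal_his:
                d6 = add_species(_site_tag("deoxy6c", i, n), per_site_protein)
                add_gating(site, d6, d5)
                members.append(d6)
                spectral[d6] = ("deoxy_6cLS", w)
                # nitrite attacks the deoxy pool; the hexacoordinate form
                # reacts at the same apparent constant (NiR is orders of
                # magnitude slower than gating, so the measured constant
                # already integrates over the gate)
                reactions.append(
                    Reaction({d6: 1, no2: 1}, {met: 1, no: 1}, k_site)
                )
            if cond.dithionite_conc > 0:
                # pseudo-first-order re-reduction by excess dithionite,
                # returning the site to its resting deoxy form
                target = d6 if site.has_distal_his else d5
                reactions.append(
                    Reaction({met: 1}, {target: 1}, K_FERRIC_REREDUCTION)
                )
            site_species.append(members)

    else:  # pragma: no cover - AssayKind() already validates
        raise SchemeConfigError(f"unknown assay kind {cond.assay_kind!r}")

    return ReactionScheme(
        species=species,
        reactions=reactions,
        y0=y0,
        site_species=site_species,
        spectral_species=spectral,
        assay_kind=kind,
    )


# ---------------------------------------------------------------------------
# integration


def _stiffness_context(scheme: ReactionScheme) -> str:
    y0 = scheme.initial_vector()
    scale = max(float(y0.max()), 1e-12)
    rates = []
    for rxn in scheme.reactions:
        order = sum(rxn.reactants.values())
        rates.append(rxn.k * scale ** max(order - 1, 0))
    rates = [r for r in rates if r > 0]
    if not rates:
        return "no active reactions"
    return (
        f"characteristic rates span {min(rates):.3g}..{max(rates):.3g} s^-1 "
        f"(ratio {max(rates) / min(rates):.3g})"
    )


def simulate(
    scheme: ReactionScheme,
    t_grid: Sequence[float],
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-14,  # M
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a reaction scheme on a fixed time grid.

    The grid must be strictly increasing and start at 0.  A stiff-capable
    integrator with dense output evaluates the solution exactly on the
    requested grid.  Trajectories are checked non-negative (to tolerance)
    and clipped at zero; per-site heme conservation is checked to within
    ``10 * rel_tol`` relative error.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise ValueError("t_grid must be a 1-D sequence")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")

    y0 = scheme.initial_vector()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    n_s = len(scheme.species)
    index = scheme.index
    n_r = len(scheme.reactions)
    S_react = np.zeros((n_r, n_s))
    S_net = np.zeros((n_r, n_s))
    ks = np.zeros(n_r)
    for j, rxn in enumerate(scheme.reactions):
        ks[j] = rxn.k
        for sp, nu in rxn.reactants.items():
            S_react[j, index[sp]] += nu
            S_net[j, index[sp]] -= nu
        for sp, nu in rxn.products.items():
            S_net[j, index[sp]] += nu

    if n_r == 0 or len(t) == 1:
        conc = np.repeat(y0[:, None], len(t), axis=1)
        return Trajectory(times=t, species=list(scheme.species), conc=conc,
                          scheme=scheme)

    S_int = S_react.astype(np.int64)
    active = S_react > 0  # (n_r, n_s)
    active_idx = [np.nonzero(active[j])[0] for j in range(n_r)]
    S_net_T = S_net.T.copy()

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        # rate_j = k_j * prod_i y_i^S[j, i]; integer powers keep the RHS
        # smooth through the tiny negative excursions the solver explores
        rates = ks * np.prod(y[None, :] ** S_int, axis=1)
        return S_net_T @ rates

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        J = np.zeros((n_s, n_s))
        for j in range(n_r):
            for i in active_idx[j]:
                dr = ks[j] * S_int[j, i]
                if S_int[j, i] > 1:
                    dr *= y[i] ** (S_int[j, i] - 1)
                for m in active_idx[j]:
                    if m != i:
                        dr *= y[m] ** S_int[j, m]
                J[:, i] += S_net[j] * dr
        return J

    scale = max(float(y0.max()), 1e-12)
    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        y0,
        method=method,
        t_eval=t,
        rtol=rel_tol,
        atol=abs_tol,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}; {_stiffness_context(scheme)}"
        )
    conc = sol.y
    floor = -(1e-6 * scale)
    if conc.min() < floor:
        raise SimulationError(
            f"negative concentrations beyond tolerance "
            f"(min {conc.min():.3g}); {_stiffness_context(scheme)}"
        )
    conc = np.clip(conc, 0.0, None)
    traj = Trajectory(times=t, species=list(scheme.species), conc=conc,
                      scheme=scheme)
    err = traj.conservation_error()
    # the conservation contract: 1e-8 relative at the default tolerances,
    # scaling with rel_tol when the caller loosens it
    if err > max(10 * rel_tol, 1e-8):
        raise SimulationError(
            f"heme conservation violated (relative drift {err:.3g}); "
            f"{_stiffness_context(scheme)}"
        )
    return traj


# convenience re-export for callers that tweak conditions
def with_conditions(cond: AssayConditions, **changes) -> AssayConditions:
    """Return a copy of ``cond`` with fields replaced."""
    return replace(cond, **changes)
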