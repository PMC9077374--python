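"""Species, reaction network, and rate-constant transformations.

The network covers the chemistry of azide (N3-) solutions under irradiation
at 25 C: the three radical-radical channels that form molecular hydrogen in
diffusing tracks, the azide / hydrazoic-acid scavenging reactions, the azide
radical chemistry, dissolved-oxygen scavenging, and a background pure-water
recombination set.  Rate constants are the observed 25 C compilation values;
they are converted to encounter radii for the IRT engine by
:func:`encounter_radius`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .units import (
    WATER_MOLARITY,
    diffusion_nm2_ps,
    k_bimolecular_nm3_ps,
)

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "EncounterParams",
    "default_network",
    "encounter_radius",
    "smoluchowski_rate",
    "ionic_strength_factor",
    "hn3_fraction",
    "scavenging_capacity",
    "PKA_HN3",
]

#: pKa of hydrazoic acid HN3 / N3- in water at 25 C.
PKA_HN3 = 4.7

_ELEMENTS = ("H", "O", "N")


@dataclass(frozen=True)
class Species:
    """A chemical entity tracked by the simulation.

    diffusion_coefficient is stored in cm^2 s^-1 (literature convention);
    :attr:`d_nm2_ps` gives the internal value.
    """

    name: str
    charge: int
    diffusion_coefficient: float  # cm^2/s
    element_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.diffusion_coefficient <= 0:
            raise ValueError(f"{self.name}: diffusion coefficient must be > 0")
        if any(v < 0 for v in self.element_counts.values()):
            raise ValueError(f"{self.name}: negative element count")

    @property
    def d_nm2_ps(self) -> float:
        return diffusion_nm2_ps(self.diffusion_coefficient)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    kind is one of ``track-pair`` (bimolecular between track particles),
    ``pseudo-first-order`` (one partner is a homogeneous bulk solute) or
    ``first-order-intrinsic`` (solvent reaction; ``rate_constant`` is still
    the bimolecular M^-1 s^-1 value and is multiplied by the water molarity
    at compile time).  ``sink=True`` marks channels whose products are not
    specified in the source compilation ("products (!= H2)"): they remove
    their reactants and are excluded from balance checks.
    """

    id: str
    reactants: tuple
    products: tuple
    rate_constant: float  # M^-1 s^-1 (bimolecular / intrinsic), s^-1 never used
    kind: str = "track-pair"
    sink: bool = False
    enabled: bool = True

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise ValueError(f"{self.id}: rate constant must be > 0")
        if self.kind not in ("track-pair", "pseudo-first-order", "first-order-intrinsic"):
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError(f"{self.id}: need 1 or 2 reactants")
        if len(self.products) > 3:
            raise ValueError(f"{self.id}: at most 3 products")


@dataclass
class ReactionNetwork:
    species: dict  # name -> Species
    reactions: list  # of Reaction
    temperature_C: float = 25.0
    pKa_table: dict = field(default_factory=lambda: {"HN3": PKA_HN3})

    def __post_init__(self):
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self):
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for name in (*r.reactants, *r.products):
                if name not in self.species:
                    raise ValueError(f"{r.id}: unknown species {name!r}")
            if not r.sink:
                self._check_balance(r)

    def _check_balance(self, rxn: Reaction):
        """Charge must balance exactly; H and O may differ by whole waters
        (the solvent is implicit), i.e. dH - 2*dO == 0; N balances exactly."""
        dq = 0
        dn = dict.fromkeys(_ELEMENTS, 0)
        for name in rxn.products:
            s = self.species[name]
            dq += s.charge
            for e in _ELEMENTS:
                dn[e] += s.element_counts.get(e, 0)
        for name in rxn.reactants:
            s = self.species[name]
            dq -= s.charge
            for e in _ELEMENTS:
                dn[e] -= s.element_counts.get(e, 0)
        if rxn.kind == "first-order-intrinsic":
            # one implicit water reactant
            dn["H"] -= 2
            dn["O"] -= 1
        if dq != 0:
            raise ValueError(f"{rxn.id}: charge imbalance {dq}")
        if dn["N"] != 0:
            raise ValueError(f"{rxn.id}: N imbalance {dn['N']}")
        if dn["H"] - 2 * dn["O"] != 0:
            raise ValueError(f"{rxn.id}: H/O imbalance beyond implicit water "
                             f"(dH={dn['H']}, dO={dn['O']})")

    # -- lookup helpers ----------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def with_rate(self, rid: str, k: float) -> "ReactionNetwork":
        """Return a copy with one rate constant replaced."""
        rxns = [replace(r, rate_constant=k) if r.id == rid else r for r in self.reactions]
        return ReactionNetwork(dict(self.species), rxns, self.temperature_C,
                               dict(self.pKa_table))

    def with_enabled(self, rid: str, enabled: bool) -> "ReactionNetwork":
        rxns = [replace(r, enabled=enabled) if r.id == rid else r for r in self.reactions]
        return ReactionNetwork(dict(self.species), rxns, self.temperature_C,
                               dict(self.pKa_table))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "temperature_C": self.temperature_C,
            "pKa_table": dict(self.pKa_table),
            "species": [
                {"name": s.name, "charge": s.charge,
                 "diffusion_coefficient": s.diffusion_coefficient,
                 "element_counts": dict(s.element_counts)}
                for s in self.species.values()
            ],
            "reactions": [
                {"id": r.id, "reactants": list(r.reactants),
                 "products": list(r.products), "rate_constant": r.rate_constant,
                 "kind": r.kind, "sink": r.sink, "enabled": r.enabled}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        species = {
            s["name"]: Species(s["name"], int(s["charge"]),
                               float(s["diffusion_coefficient"]),
                               {k: int(v) for k, v in s.get("element_counts", {}).items()})
            for s in d["species"]
        }
        reactions = [
            Reaction(r["id"], tuple(r["reactants"]), tuple(r.get("products", [])),
                     float(r["rate_constant"]), r.get("kind", "track-pair"),
                     bool(r.get("sink", False)), bool(r.get("enabled", True)))
            for r in d["reactions"]
        ]
        return cls(species, reactions, float(d.get("temperature_C", 25.0)),
                   dict(d.get("pKa_table", {"HN3": PKA_HN3})))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Default species table.  Diffusion coefficients in 1e-5 cm^2/s at 25 C from
# the standard radiolysis compilations; D(N3-) = D(N3) = 1.84e-5 cm^2/s.
# ---------------------------------------------------------------------------

def _sp(name, charge, d5, **elems):
    return Species(name, charge, d5 * 1e-5, elems)


_DEFAULT_SPECIES = [
    _sp("e_aq-", -1, 4.90),
    _sp("H", 0, 7.00, H=1),
    _sp("H2", 0, 4.80, H=2),
    _sp("OH", 0, 2.20, H=1, O=1),
    _sp("OH-", -1, 5.27, H=1, O=1),
    _sp("H3O+", +1, 9.46, H=3, O=1),
    _sp("H2O2", 0, 2.30, H=2, O=2),
    _sp("O2", 0, 2.40, O=2),
    _sp("O2-", -1, 1.75, O=2),
    _sp("HO2", 0, 2.30, H=1, O=2),
    _sp("N3-", -1, 1.84, N=3),
    _sp("N3", 0, 1.84, N=3),
    _sp("HN3", 0, 2.00, H=1, N=3),
    _sp("HN3-", -1, 1.80, H=1, N=3),
    _sp("(N3)2-", -1, 1.50, N=6),
    _sp("N2", 0, 2.00, N=2),
]


def _rx(rid, reactants, products, k, kind="track-pair", sink=False, enabled=True):
    return Reaction(rid, tuple(reactants), tuple(products), k, kind, sink, enabled)


# The azide / hydrogen scheme (observed 25 C rate constants, M^-1 s^-1).
# k5, k10 and k13 are printed in the source compilation only as bounds;
# the bound value is used (results are insensitive: the chemistry is designed
# around the near-inertness of e_aq- towards N3-).  k6 is a proton-transfer
# range 1e9-1e10; the diffusion-controlled upper end is the default.  The
# explicit in-track protonation channel R6 is disabled by default: at neutral
# pH the acid-base speciation is applied as a static partition instead.
_CORE_REACTIONS = [
    _rx("R1", ("e_aq-", "H"), ("H2", "OH-"), 2.5e10),
    _rx("R2", ("e_aq-", "e_aq-"), ("H2", "OH-", "OH-"), 6.2e9),
    _rx("R3", ("H", "H"), ("H2",), 4.6e9),
    _rx("R4", ("N3-", "H"), ("HN3-",), 3.15e9, kind="pseudo-first-order"),
    _rx("R5", ("N3-", "e_aq-"), (), 1.5e6, kind="pseudo-first-order", sink=True),
    _rx("R6", ("N3-", "H3O+"), ("HN3",), 1.0e10, kind="pseudo-first-order",
        enabled=False),
    _rx("R7", ("HN3", "e_aq-"), ("HN3-",), 1.2e10, kind="pseudo-first-order"),
    _rx("R8", ("HN3", "H"), (), 6.3e7, kind="pseudo-first-order", sink=True),
    _rx("R9", ("N3-", "OH"), ("N3", "OH-"), 1.2e10, kind="pseudo-first-order"),
    _rx("R10", ("HN3", "OH"), ("N3",), 1.0e7, kind="pseudo-first-order"),
    _rx("R11", ("N3", "e_aq-"), ("N3-",), 2.4e10),
    _rx("R12", ("N3", "H"), ("HN3",), 1.0e10),
    _rx("R13", ("N3", "H2O2"), (), 5.0e6, sink=True),
    _rx("R14", ("N3", "N3"), ("N2", "N2", "N2"), 3.9e9),
    _rx("R15", ("N3", "N3-"), ("(N3)2-",), 2.4e5, kind="pseudo-first-order"),
    _rx("R16", ("N3", "O2-"), ("O2", "N3-"), 1.2e10),
    _rx("R17", ("e_aq-",), ("H", "OH-"), 19.0, kind="first-order-intrinsic"),
]

# Background pure-water recombination/scavenging set at 25 C (compilation
# values; the exact scheme is configurable and round-trips through YAML).
_WATER_REACTIONS = [
    _rx("W1", ("OH", "OH"), ("H2O2",), 5.5e9),
    _rx("W2", ("e_aq-", "OH"), ("OH-",), 3.5e10),
    _rx("W3", ("H", "OH"), (), 7.0e9),           # -> H2O
    _rx("W4", ("e_aq-", "H2O2"), ("OH", "OH-"), 1.36e10),
    _rx("W5", ("H", "H2O2"), ("OH",), 9.0e7),    # + H2O
    _rx("W6", ("e_aq-", "H3O+"), ("H",), 2.3e10),
    _rx("W7", ("OH-", "H3O+"), (), 1.1e11),      # -> 2 H2O
    _rx("W8", ("e_aq-", "O2"), ("O2-",), 1.9e10),
    _rx("W9", ("H", "O2"), ("HO2",), 2.1e10),
    _rx("W10", ("OH", "H2"), ("H",), 4.0e7),     # + H2O; consumes H2
    _rx("W11", ("OH", "H2O2"), ("HO2",), 2.7e7),  # + H2O
    _rx("W12", ("H", "OH-"), ("e_aq-",), 2.2e7),  # + H2O
]


def default_network(rate_overrides: dict | None = None,
                    extra_reactions: list | None = None) -> ReactionNetwork:
    """Build the default 25 C reaction network.

    Parameters
    ----------
    rate_overrides : mapping reaction-id -> rate constant (M^-1 s^-1), applied
        on top of the defaults.
    extra_reactions : additional :class:`Reaction` objects to append.
    """
    species = {s.name: s for s in _DEFAULT_SPECIES}
    reactions = list(_CORE_REACTIONS) + list(_WATER_REACTIONS)
    if extra_reactions:
        reactions.extend(extra_reactions)
    net = ReactionNetwork(species, reactions)
    if rate_overrides:
        for rid, k in rate_overrides.items():
            net = net.with_rate(rid, k)
    return net


# ---------------------------------------------------------------------------
# Rate-constant transformations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncounterParams:
    """Geometric IRT parameters equivalent to an observed rate constant.

    ``radius_nm`` is the encounter radius; ``v_nm_ps`` the surface reaction
    velocity of the radiation boundary condition (None for a fully
    diffusion-controlled, perfectly absorbing contact).
    """

    radius_nm: float
    v_nm_ps: float | None = None


def encounter_radius(k_obs: float, d_mutual: float, model: str = "fully-diffusion-controlled",
                     k_act: float | None = None):
    """Convert an observed bimolecular rate constant to IRT contact geometry.

    Parameters
    ----------
    k_obs : observed rate constant, M^-1 s^-1.
    d_mutual : mutual diffusion coefficient D_A + D_B, cm^2/s.
    model : ``fully-diffusion-controlled`` returns the Smoluchowski radius R
        with k_obs = 4 pi N_A D R.  ``partially-controlled`` additionally
        needs ``k_act`` (M^-1 s^-1) and returns the larger Smoluchowski
        radius of the diffusion-limited part together with the surface
        velocity of the radiation boundary condition, chosen so that the
        long-time Collins-Kimball rate 1/k_obs = 1/k_diff + 1/k_act is
        reproduced.
    """
    if k_obs <= 0 or d_mutual <= 0:
        raise ValueError("k_obs and d_mutual must be positive")
    d = diffusion_nm2_ps(d_mutual)
    if model == "fully-diffusion-controlled":
        radius = k_bimolecular_nm3_ps(k_obs) / (4.0 * math.pi * d)
        return EncounterParams(radius_nm=radius)
    if model == "partially-controlled":
        if k_act is None:
            raise ValueError("partially-controlled model needs k_act")
        if k_act <= k_obs:
            raise ValueError("unphysical: k_act must exceed k_obs "
                             "(observed rate cannot outrun the intrinsic rate)")
        k_diff = k_obs * k_act / (k_act - k_obs)
        radius = k_bimolecular_nm3_ps(k_diff) / (4.0 * math.pi * d)
        v = k_bimolecular_nm3_ps(k_act) / (4.0 * math.pi * radius ** 2)
        return EncounterParams(radius_nm=radius, v_nm_ps=v)
    raise ValueError(f"unknown model {model!r}")


def smoluchowski_rate(radius_nm: float, d_mutual: float) -> float:
    """Forward Smoluchowski rate k = 4 pi N_A D R, returned in M^-1 s^-1."""
    d = diffusion_nm2_ps(d_mutual)
    return 4.0 * math.pi * d * radius_nm / k_bimolecular_nm3_ps(1.0)


def ionic_strength_factor(z_a: int, z_b: int, ionic_strength: float) -> float:
    """Bronsted-Bjerrum / extended Debye-Hueckel salt correction at 25 C.

    k(I) = f * k(I=0) with log10 f = 1.02 zA zB sqrt(I) / (1 + sqrt(I)).
    f = 1 for a neutral partner or at zero ionic strength; f > 1 for like
    charges, f < 1 for unlike charges.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if z_a == 0 or z_b == 0 or ionic_strength == 0.0:
        return 1.0
    s = math.sqrt(ionic_strength)
    return 10.0 ** (1.02 * z_a * z_b * s / (1.0 + s))


def hn3_fraction(pH: float, pKa: float = PKA_HN3) -> float:
    """Fraction of total azide present as hydrazoic acid HN3 at a given pH.

    Henderson-Hasselbalch speciation: 1 / (1 + 10^(pH - pKa)).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH out of range [0, 14]")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def scavenging_capacity(k: float, conc: float) -> float:
    """Pseudo-first-order scavenging power k[S] in s^-1 (reciprocal is the
    scavenging time)."""
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return k * conc


def intrinsic_first_order_rate(k_bimolecular: float) -> float:
    """s^-1 rate of a solvent reaction written with a bimolecular constant."""
    return k_bimolecular * WATER_MOLARITY
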