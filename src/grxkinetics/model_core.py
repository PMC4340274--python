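"""Declarative mass-action models of the glutaredoxin (Grx) redox cycle.

Glutaredoxins catalyse deglutathionylation — removal of the glutathione
adduct from a protein mixed disulphide (PSSG -> PSH) — and are re-reduced
by GSH, which glutathione reductase (GR) regenerates from GSSG at NADPH's
expense.  This module builds the four kinetic models used throughout the
package as plain stoichiometry + rate-law objects:

* the wild-type dithiol core (two reactions, second order in GSH),
* the active-site-mutant core (single-cysteine cycle, first order in GSH),
* the GR-coupled three-reaction system with an optionally reversible
  deglutathionylation step, and
* the HED activity-assay model (GR + Grx reduction + lumped HED reduction)
  parameterised for the yeast Grx1/Grx2 systems.

All concentrations are in uM and all times in seconds.  Models are
immutable value objects; clamped species act as fixed boundary
concentrations and every Grx/glutathione moiety is registered as an
explicit conservation relation so the solver can reduce the system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "KineticParameters",
    "Species",
    "Reaction",
    "Moiety",
    "ModelSpec",
    "InvalidModelError",
    "ConfigurationError",
    "PARAMETER_UNITS",
    "GRX1_BACKGROUND",
    "GRX2_BACKGROUND",
    "build_wildtype_core",
    "build_mutant_core",
    "build_ecoli_system",
    "build_hed_assay",
    "mass_action_rate",
    "generic_two_substrate_rate",
    "reaction_rate",
]


class InvalidModelError(ValueError):
    """A model builder was given parameters that admit no valid model."""


class ConfigurationError(ValueError):
    """A configuration or concentration table is missing or malformed."""


# Units carried per parameter field.  k2_wt (uM^-2 s^-1, two GSH) and
# k2p_mut (uM^-1 s^-1, one GSH) are dimensionally distinct and must never
# be interchanged.
PARAMETER_UNITS: Mapping[str, str] = MappingProxyType(
    {
        "k1": "uM^-1.s^-1",
        "k2_wt": "uM^-2.s^-1",
        "k2p_mut": "uM^-1.s^-1",
        "k_hed": "uM^-1.s^-1",
        "keq_deglut": "uM",
        "gr_kcat": "s^-1",
        "gr_K_NADPH": "uM",
        "gr_K_GSSG": "uM",
        "gr_conc": "uM",
        "grx_tot": "uM",
    }
)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and enzyme parameters of the Grx system (uM, s).

    Defaults are the yeast Grx1 values: the fitted deglutathionylation /
    HED-reduction constant 0.073 uM^-1 s^-1, the GSH-oxidation constant
    4.23e-6 uM^-2 s^-1, and the standard yeast glutathione-reductase
    parameters (kcat 900 s^-1, K_NADPH 15 uM, K_GSSG 74.6 uM, 0.02 uM
    enzyme).  ``grx_tot`` is the total glutaredoxin moiety.
    """

    k1: float = 0.073          # deglutathionylation, uM^-1 s^-1
    k2_wt: float = 4.23e-6     # wild-type GrxSS reduction by 2 GSH, uM^-2 s^-1
    k2p_mut: float = 4.2e-3    # mutant GrxSSG reduction by 1 GSH, uM^-1 s^-1
    k_hed: float = 0.073       # lumped HED reduction, uM^-1 s^-1
    keq_deglut: float = 1.0    # equilibrium constant of deglutathionylation, uM
    gr_kcat: float = 900.0     # s^-1
    gr_K_NADPH: float = 15.0   # uM
    gr_K_GSSG: float = 74.6    # uM
    gr_conc: float = 0.02      # uM
    grx_tot: float = 0.24      # uM

    def units(self) -> Mapping[str, str]:
        return PARAMETER_UNITS

    def replace(self, **updates: float) -> "KineticParameters":
        unknown = set(updates) - set(PARAMETER_UNITS)
        if unknown:
            raise ConfigurationError(
                f"unknown kinetic parameter(s): {sorted(unknown)}"
            )
        return replace(self, **updates)


#: Background species concentrations of the yeast HED-assay models (uM).
GRX1_BACKGROUND: Mapping[str, float] = MappingProxyType(
    {
        "NADPH": 250.0,
        "NADP": 1.0,
        "GSH": 998.0,
        "GSSG": 1.0,
        "HED": 70.0,
        "GrxSH2": 0.12,
        "GrxSS": 0.12,
    }
)

GRX2_BACKGROUND: Mapping[str, float] = MappingProxyType(
    {
        "NADPH": 250.0,
        "NADP": 1.0,
        "GSH": 998.0,
        "GSSG": 1.0,
        "HED": 70.0,
        "GrxSH2": 0.02,
        "GrxSS": 0.02,
    }
)

#: Fitted rate constants of the yeast HED-assay fits (uM-based units).
GRX1_FITTED = MappingProxyType({"k2_wt": 4.23e-6, "k_hed": 0.073})
GRX2_FITTED = MappingProxyType({"k2_wt": 6.74e-5, "k_hed": 0.252})


@dataclass(frozen=True)
class Species:
    name: str
    role: str  # "dynamic" | "clamped"
    conc: float  # initial (dynamic) or fixed (clamped) concentration, uM

    def __post_init__(self) -> None:
        if self.role not in ("dynamic", "clamped"):
            raise InvalidModelError(f"species {self.name}: bad role {self.role!r}")
        if not (self.conc >= 0.0):
            raise InvalidModelError(
                f"species {self.name}: negative concentration {self.conc}"
            )


def _freeze(mapping: Mapping[str, float] | None) -> Mapping[str, float]:
    return MappingProxyType(dict(mapping or {}))


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry plus a rate law.

    ``constants`` holds the resolved numeric constants of the rate law;
    ``param_refs`` maps each constant slot back to the KineticParameters
    field it came from, so a fitted parameter can be substituted without
    rebuilding the model by hand.  ``reverse_order`` gives the kinetic
    orders of the reverse term of a reversible mass-action law.
    """

    id: str
    stoichiometry: Mapping[str, int]
    kinetic_order: Mapping[str, float]
    rate_law: str  # mass_action_irreversible | mass_action_reversible | generic_two_substrate
    constants: Mapping[str, float]
    param_refs: Mapping[str, str] = field(default_factory=dict)
    reverse_order: Mapping[str, float] = field(default_factory=dict)
    substrates: tuple[str, ...] = ()  # (A, B) of the generic two-substrate law

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", _freeze(self.stoichiometry))
        object.__setattr__(self, "kinetic_order", _freeze(self.kinetic_order))
        object.__setattr__(self, "constants", _freeze(self.constants))
        object.__setattr__(self, "param_refs", _freeze(self.param_refs))
        object.__setattr__(self, "reverse_order", _freeze(self.reverse_order))
        if self.rate_law == "mass_action_reversible":
            keq = self.constants.get("keq", float("nan"))
            if not (math.isfinite(keq) and keq > 0):
                raise InvalidModelError(
                    f"reaction {self.id}: reversible law needs a finite "
                    f"positive equilibrium constant, got {keq}"
                )


@dataclass(frozen=True)
class Moiety:
    """A conserved linear combination of species concentrations."""

    name: str
    members: Mapping[str, int]  # species -> multiplicity in the conserved sum
    total: float  # uM

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", _freeze(self.members))


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------


def mass_action_rate(
    k: float,
    concentrations: Mapping[str, float],
    kinetic_order: Mapping[str, float],
    keq: float | None = None,
    reverse_order: Mapping[str, float] | None = None,
) -> float:
    """Mass-action flux k * prod(c_i^n_i), optionally net of a reverse term.

    The reversible form is ``k * (forward - reverse / keq)`` with the
    reverse product taken over ``reverse_order`` — i.e. the reverse rate
    constant is ``k / keq``, so the net rate vanishes exactly when the
    mass-action ratio equals ``keq``.
    """
    forward = 1.0
    for name, order in kinetic_order.items():
        c = concentrations[name]
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
        forward *= c ** order
    if keq is None:
        return k * forward
    if reverse_order is None:
        raise ValueError("reversible mass-action law needs reverse_order")
    reverse = 1.0
    for name, order in reverse_order.items():
        c = concentrations[name]
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
        reverse *= c ** order
    return k * (forward - reverse / keq)


def generic_two_substrate_rate(
    kcat: float, E: float, A: float, Ka: float, B: float, Kb: float
) -> float:
    """Irreversible generic two-substrate rate, separable in each substrate.

    v = kcat*E * (A/Ka)(B/Kb) / ((1 + A/Ka)(1 + B/Kb)); saturates at
    kcat*E and reduces to Michaelis-Menten in either substrate when the
    other is held fixed.
    """
    if Ka <= 0 or Kb <= 0:
        raise ValueError("half-saturation constants must be positive")
    if A < 0 or B < 0:
        raise ValueError("substrate concentrations must be non-negative")
    a = A / Ka
    b = B / Kb
    return kcat * E * (a * b) / ((1.0 + a) * (1.0 + b))


def reaction_rate(rxn: Reaction, conc: Mapping[str, float]) -> float:
    """Evaluate one reaction's rate law at the given concentrations."""
    if rxn.rate_law == "mass_action_irreversible":
        return mass_action_rate(rxn.constants["k"], conc, rxn.kinetic_order)
    if rxn.rate_law == "mass_action_reversible":
        return mass_action_rate(
            rxn.constants["k"],
            conc,
            rxn.kinetic_order,
            keq=rxn.constants["keq"],
            reverse_order=rxn.reverse_order,
        )
    if rxn.rate_law == "generic_two_substrate":
        a_name, b_name = rxn.substrates
        return generic_two_substrate_rate(
            rxn.constants["kcat"],
            rxn.constants["E"],
            conc[a_name],
            rxn.constants["Ka"],
            conc[b_name],
            rxn.constants["Kb"],
        )
    raise InvalidModelError(f"reaction {rxn.id}: unknown rate law {rxn.rate_law!r}")


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A reaction network: species, reactions, conservation relations.

    ``measured_reaction`` names the reaction whose steady-state flux is the
    experimental observable (NADPH consumption through GR for the assay
    models, the GSH-oxidation step for the two-reaction cores; at steady
    state all cycle fluxes coincide).
    """

    name: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    conservation: tuple[Moiety, ...] = ()
    measured_reaction: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InvalidModelError(f"model {self.name}: duplicate species")
        known = set(names)
        for rxn in self.reactions:
            for sp in (*rxn.stoichiometry, *rxn.kinetic_order, *rxn.reverse_order):
                if sp not in known:
                    raise InvalidModelError(
                        f"model {self.name}: reaction {rxn.id} references "
                        f"unknown species {sp!r}"
                    )
        # every reaction must leave every registered moiety sum unchanged,
        # counting only the moiety's own members among *dynamic* species
        clamped = {s.name for s in self.species if s.role == "clamped"}
        for moiety in self.conservation:
            for rxn in self.reactions:
                net = sum(
                    mult * rxn.stoichiometry.get(sp, 0)
                    for sp, mult in moiety.members.items()
                    if sp not in clamped
                )
                if net != 0:
                    raise InvalidModelError(
                        f"model {self.name}: reaction {rxn.id} changes "
                        f"conserved moiety {moiety.name!r} by {net}"
                    )
        if self.measured_reaction and self.measured_reaction not in {
            r.id for r in self.reactions
        }:
            raise InvalidModelError(
                f"model {self.name}: unknown measured reaction "
                f"{self.measured_reaction!r}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def dynamic_species(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role == "dynamic")

    @property
    def clamped(self) -> Mapping[str, float]:
        return {s.name: s.conc for s in self.species if s.role == "clamped"}

    def initial_state(self) -> dict[str, float]:
        return {s.name: s.conc for s in self.species}

    def reaction(self, reaction_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == reaction_id:
                return rxn
        raise KeyError(f"model {self.name}: no reaction {reaction_id!r}")

    # -- derived model variants --------------------------------------------

    def with_clamped(self, name: str, value: float) -> "ModelSpec":
        """A copy with one clamped species set to a new fixed value."""
        if value < 0:
            raise ValueError(f"clamped {name} must be non-negative, got {value}")
        new_species = []
        found = False
        for sp in self.species:
            if sp.name == name:
                if sp.role != "clamped":
                    raise InvalidModelError(
                        f"model {self.name}: {name} is not clamped"
                    )
                new_species.append(Species(name, "clamped", value))
                found = True
            else:
                new_species.append(sp)
        if not found:
            raise KeyError(f"model {self.name}: no species {name!r}")
        return replace(self, species=tuple(new_species))

    def with_params(self, updates: Mapping[str, float]) -> "ModelSpec":
        """A copy with rate constants substituted via their parameter refs.

        ``updates`` maps KineticParameters field names (e.g. ``k2_wt``)
        to new values; every reaction constant whose ``param_refs`` entry
        points at an updated field is replaced.
        """
        unknown = set(updates) - set(PARAMETER_UNITS)
        if unknown:
            raise ConfigurationError(
                f"unknown kinetic parameter(s): {sorted(unknown)}"
            )
        new_reactions = []
        for rxn in self.reactions:
            consts = dict(rxn.constants)
            changed = False
            for slot, ref in rxn.param_refs.items():
                if ref in updates:
                    consts[slot] = float(updates[ref])
                    changed = True
            new_reactions.append(
                replace(rxn, constants=consts) if changed else rxn
            )
        return replace(self, reactions=tuple(new_reactions))


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _check_positive(params: KineticParameters, *fields: str) -> None:
    for f in fields:
        value = getattr(params, f)
        if not (value > 0):
            raise InvalidModelError(
                f"parameter {f} must be strictly positive, got {value}"
            )


def build_wildtype_core(
    params: KineticParameters,
    pssG_clamped: float,
    gsh_clamped: float,
) -> ModelSpec:
    """Two-reaction wild-type dithiol core with clamped PSSG and GSH.

    v1: GrxSH2 + PSSG -> GrxSS + PSH + GSH   rate k1*[PSSG][GrxSH2]
    v2: GrxSS + 2 GSH -> GrxSH2 + GSSG       rate k2*[GrxSS][GSH]^2

    The Grx moiety GrxSH2 + GrxSS = grx_tot is registered; the dynamic
    state starts fully reduced (GrxSS = 0).
    """
    _check_positive(params, "k1", "k2_wt", "grx_tot")
    if pssG_clamped < 0 or gsh_clamped < 0:
        raise InvalidModelError("clamped concentrations must be non-negative")
    species = (
        Species("GrxSH2", "dynamic", params.grx_tot),
        Species("GrxSS", "dynamic", 0.0),
        Species("PSSG", "clamped", pssG_clamped),
        Species("GSH", "clamped", gsh_clamped),
        Species("PSH", "clamped", 0.0),
        Species("GSSG", "clamped", 0.0),
    )
    reactions = (
        Reaction(
            id="v1",
            stoichiometry={"GrxSH2": -1, "PSSG": -1, "GrxSS": 1, "PSH": 1, "GSH": 1},
            kinetic_order={"PSSG": 1, "GrxSH2": 1},
            rate_law="mass_action_irreversible",
            constants={"k": params.k1},
            param_refs={"k": "k1"},
        ),
        Reaction(
            id="v2",
            stoichiometry={"GrxSS": -1, "GSH": -2, "GrxSH2": 1, "GSSG": 1},
            kinetic_order={"GrxSS": 1, "GSH": 2},
            rate_law="mass_action_irreversible",
            constants={"k": params.k2_wt},
            param_refs={"k": "k2_wt"},
        ),
    )
    conservation = (
        Moiety("Grx", {"GrxSH2": 1, "GrxSS": 1}, params.grx_tot),
    )
    return ModelSpec(
        name="wildtype_core",
        species=species,
        reactions=reactions,
        conservation=conservation,
        measured_reaction="v2",
    )


def build_mutant_core(
    params: KineticParameters,
    pssG_clamped: float,
    gsh_clamped: float,
) -> ModelSpec:
    """Two-reaction single-cysteine mutant core (first order in GSH).

    v1: GrxSH + PSSG -> GrxSSG + PSH     rate k1*[PSSG][GrxSH]
    v2: GrxSSG + GSH -> GrxSH + GSSG     rate k2'*[GrxSSG][GSH]
    """
    _check_positive(params, "k1", "k2p_mut", "grx_tot")
    if pssG_clamped < 0 or gsh_clamped < 0:
        raise InvalidModelError("clamped concentrations must be non-negative")
    species = (
        Species("GrxSH", "dynamic", params.grx_tot),
        Species("GrxSSG", "dynamic", 0.0),
        Species("PSSG", "clamped", pssG_clamped),
        Species("GSH", "clamped", gsh_clamped),
        Species("PSH", "clamped", 0.0),
        Species("GSSG", "clamped", 0.0),
    )
    reactions = (
        Reaction(
            id="v1",
            stoichiometry={"GrxSH": -1, "PSSG": -1, "GrxSSG": 1, "PSH": 1},
            kinetic_order={"PSSG": 1, "GrxSH": 1},
            rate_law="mass_action_irreversible",
            constants={"k": params.k1},
            param_refs={"k": "k1"},
        ),
        Reaction(
            id="v2",
            stoichiometry={"GrxSSG": -1, "GSH": -1, "GrxSH": 1, "GSSG": 1},
            kinetic_order={"GrxSSG": 1, "GSH": 1},
            rate_law="mass_action_irreversible",
            constants={"k": params.k2p_mut},
            param_refs={"k": "k2p_mut"},
        ),
    )
    conservation = (
        Moiety("Grx", {"GrxSH": 1, "GrxSSG": 1}, params.grx_tot),
    )
    return ModelSpec(
        name="mutant_core",
        species=species,
        reactions=reactions,
        conservation=conservation,
        measured_reaction="v2",
    )


#: Default clamped boundary concentrations of the GR-coupled system (uM).
ECOLI_DEFAULT_CLAMPS: Mapping[str, float] = MappingProxyType(
    {"NADPH": 250.0, "NADP": 1.0, "GSH": 1000.0, "PSSG": 5.0, "PSH": 1.0}
)


def build_ecoli_system(
    params: KineticParameters,
    reversible: bool = False,
    clamped: Mapping[str, float] | None = None,
) -> ModelSpec:
    """Three-reaction GR-coupled Grx system for reciprocal-plot protocols.

    GR:     NADPH + GSSG -> 2 GSH + NADP    (generic two-substrate law)
    grx_red: GrxSS + 2 GSH -> GrxSH2 + GSSG  rate k2*[GrxSS][GSH]^2
    deglut: GrxSH2 + PSSG -> GrxSS + PSH + GSH  rate k1*[GrxSH2][PSSG],
            optionally net-reversible with
            v = k1*([GrxSH2][PSSG] - [GrxSS][PSH][GSH]/Keq).

    NADPH/NADP must be clamped; PSSG, GSH (and PSH in the reversible
    variant) are clamped per protocol curve; GSSG is dynamic and settles
    where the GR flux balances GSH oxidation.
    """
    _check_positive(params, "k1", "k2_wt", "grx_tot", "gr_kcat", "gr_conc")
    clamps = dict(ECOLI_DEFAULT_CLAMPS)
    clamps.update(clamped or {})
    # a None value drops a default clamp from the boundary set
    clamps = {k: v for k, v in clamps.items() if v is not None}
    for required in ("NADPH", "NADP"):
        if required not in clamps:
            raise InvalidModelError(f"clamped set must include {required}")
    if reversible:
        if not (params.keq_deglut > 0):
            raise InvalidModelError("reversible variant needs keq_deglut > 0")
        if "PSH" not in clamps:
            raise InvalidModelError(
                "reversible deglutathionylation needs a clamped PSH species"
            )
    species = [
        Species("GrxSH2", "dynamic", params.grx_tot),
        Species("GrxSS", "dynamic", 0.0),
        Species("GSSG", "dynamic", 1.0),
    ]
    for name, value in clamps.items():
        if value < 0:
            raise InvalidModelError(f"clamped {name} must be non-negative")
        species.append(Species(name, "clamped", value))
    if "PSH" not in clamps:
        species.append(Species("PSH", "clamped", 0.0))

    if reversible:
        deglut = Reaction(
            id="deglut",
            stoichiometry={"GrxSH2": -1, "PSSG": -1, "GrxSS": 1, "PSH": 1, "GSH": 1},
            kinetic_order={"GrxSH2": 1, "PSSG": 1},
            rate_law="mass_action_reversible",
            constants={"k": params.k1, "keq": params.keq_deglut},
            param_refs={"k": "k1", "keq": "keq_deglut"},
            reverse_order={"GrxSS": 1, "PSH": 1, "GSH": 1},
        )
    else:
        deglut = Reaction(
            id="deglut",
            stoichiometry={"GrxSH2": -1, "PSSG": -1, "GrxSS": 1, "PSH": 1, "GSH": 1},
            kinetic_order={"GrxSH2": 1, "PSSG": 1},
            rate_law="mass_action_irreversible",
            constants={"k": params.k1},
            param_refs={"k": "k1"},
        )
    reactions = (
        Reaction(
            id="GR",
            stoichiometry={"NADPH": -1, "GSSG": -1, "GSH": 2, "NADP": 1},
            kinetic_order={"NADPH": 1, "GSSG": 1},
            rate_law="generic_two_substrate",
            constants={
                "kcat": params.gr_kcat,
                "E": params.gr_conc,
                "Ka": params.gr_K_NADPH,
                "Kb": params.gr_K_GSSG,
            },
            param_refs={
                "kcat": "gr_kcat",
                "E": "gr_conc",
                "Ka": "gr_K_NADPH",
                "Kb": "gr_K_GSSG",
            },
            substrates=("NADPH", "GSSG"),
        ),
        Reaction(
            id="grx_red",
            stoichiometry={"GrxSS": -1, "GSH": -2, "GrxSH2": 1, "GSSG": 1},
            kinetic_order={"GrxSS": 1, "GSH": 2},
            rate_law="mass_action_irreversible",
            constants={"k": params.k2_wt},
            param_refs={"k": "k2_wt"},
        ),
        deglut,
    )
    conservation = [Moiety("Grx", {"GrxSH2": 1, "GrxSS": 1}, params.grx_tot)]
    return ModelSpec(
        name="ecoli_reversible" if reversible else "ecoli_irreversible",
        species=tuple(species),
        reactions=reactions,
        conservation=tuple(conservation),
        measured_reaction="deglut",
    )


_BACKGROUND_FIELDS = ("NADPH", "NADP", "GSH", "GSSG", "HED", "GrxSH2", "GrxSS")


def build_hed_assay(
    params: KineticParameters,
    background: Mapping[str, float] | None = None,
) -> ModelSpec:
    """GR-coupled HED activity-assay model (yeast Grx1/Grx2 systems).

    Three reactions: GR (generic two-substrate), Grx reduction (second
    order in GSH, constant k2_wt) and a lumped HED reduction
    GrxSH2 + HED -> GrxSS with rate k_hed*[GrxSH2][HED].  The lumped step
    nets out the spontaneous GSH + HED pre-reaction, so it carries no
    glutathione stoichiometry and the closed pool GSH + 2*GSSG is
    conserved while glutathione cycles through GR.  NADPH/NADP and HED
    are clamped; the measured observable is the GR (NADPH-consumption)
    flux, which equals the HED-reduction flux at steady state.
    """
    _check_positive(params, "k2_wt", "gr_kcat", "gr_conc")
    if params.k_hed < 0:
        raise InvalidModelError("k_hed must be non-negative")
    conc = dict(GRX1_BACKGROUND)
    if background is not None:
        conc = dict(background)
    missing = [f for f in _BACKGROUND_FIELDS if f not in conc]
    if missing:
        raise ConfigurationError(
            f"concentration table is missing field(s): {missing}"
        )
    grx_tot = conc["GrxSH2"] + conc["GrxSS"]
    if not (grx_tot > 0):
        raise InvalidModelError("total Grx must be strictly positive")
    species = (
        Species("NADPH", "clamped", conc["NADPH"]),
        Species("NADP", "clamped", conc["NADP"]),
        Species("HED", "clamped", conc["HED"]),
        Species("GSH", "dynamic", conc["GSH"]),
        Species("GSSG", "dynamic", conc["GSSG"]),
        Species("GrxSH2", "dynamic", conc["GrxSH2"]),
        Species("GrxSS", "dynamic", conc["GrxSS"]),
    )
    reactions = (
        Reaction(
            id="GR",
            stoichiometry={"NADPH": -1, "GSSG": -1, "GSH": 2, "NADP": 1},
            kinetic_order={"NADPH": 1, "GSSG": 1},
            rate_law="generic_two_substrate",
            constants={
                "kcat": params.gr_kcat,
                "E": params.gr_conc,
                "Ka": params.gr_K_NADPH,
                "Kb": params.gr_K_GSSG,
            },
            param_refs={
                "kcat": "gr_kcat",
                "E": "gr_conc",
                "Ka": "gr_K_NADPH",
                "Kb": "gr_K_GSSG",
            },
            substrates=("NADPH", "GSSG"),
        ),
        Reaction(
            id="grx_red",
            stoichiometry={"GrxSS": -1, "GSH": -2, "GrxSH2": 1, "GSSG": 1},
            kinetic_order={"GrxSS": 1, "GSH": 2},
            rate_law="mass_action_irreversible",
            constants={"k": params.k2_wt},
            param_refs={"k": "k2_wt"},
        ),
        Reaction(
            id="hed_red",
            stoichiometry={"GrxSH2": -1, "HED": -1, "GrxSS": 1},
            kinetic_order={"GrxSH2": 1, "HED": 1},
            rate_law="mass_action_irreversible",
            constants={"k": params.k_hed},
            param_refs={"k": "k_hed"},
        ),
    )
    conservation = (
        Moiety("Grx", {"GrxSH2": 1, "GrxSS": 1}, grx_tot),
        Moiety("glutathione", {"GSH": 1, "GSSG": 2}, conc["GSH"] + 2 * conc["GSSG"]),
    )
    return ModelSpec(
        name="hed_assay",
        species=species,
        reactions=reactions,
        conservation=conservation,
        measured_reaction="GR",
    )
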