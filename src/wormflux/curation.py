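"""Targeted curation operations: biomass/GAM installation, growth-medium
construction, quinone-coupled enzyme relocation and intermembrane shuttles.

The quinone fix and the shuttles together reproduce a recurring eukaryotic
modelling problem: an inner-membrane enzyme (dihydroorotate dehydrogenase)
whose substrate pool lives in the cytosol.  Relocating the enzyme to the
inner membrane — substrate side facing the intermembrane space, electron
acceptor the mitochondrial quinone pool — plus *technical* outer-membrane
shuttles (the outer membrane is freely permeable to small molecules) makes
the pathway operational without inventing biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .core import (
    FLAG_BIOMASS,
    FLAG_TRANSPORTER,
    MetabolicModel,
    ModelError,
    Reaction,
    check_balance,
)

__all__ = [
    "BiomassSpec",
    "MediumSpec",
    "install_biomass",
    "install_medium",
    "fix_quinone_coupled_enzyme",
    "add_intermembrane_shuttle",
]

BIOMASS_ID = "BIOMASS"


@dataclass
class BiomassSpec:
    """Biomass composition plus growth-associated maintenance (GAM).

    ``components`` maps metabolite ids to positive consumption coefficients;
    ``gam`` is the ATP hydrolyzed per unit biomass (dimensionless
    stoichiometric coefficient, >= 0).
    """

    components: dict[str, Fraction]
    gam: float = 20.0
    compartment: str = "c"  # where the ATP-hydrolysis bookkeeping lives

    def __post_init__(self):
        if self.gam < 0:
            raise ValueError("gam must be >= 0")
        self.components = {m: Fraction(c) for m, c in self.components.items()}


@dataclass
class MediumSpec:
    """Uptake caps keyed by *extracellular metabolite id*."""

    uptakes: dict[str, float]
    description: str = ""

    def __post_init__(self):
        for met, rate in self.uptakes.items():
            if rate < 0:
                raise ValueError(f"negative uptake for {met!r}")


def _energy_species(model: MetabolicModel, compartment: str) -> dict[str, str]:
    ids = {}
    for base in ("atp", "adp", "pi", "h", "h2o"):
        met = model.find_metabolite(base, compartment)
        if met is None:
            raise ModelError(
                f"cannot locate {base!r} in compartment {compartment!r} for "
                "ATP-maintenance bookkeeping"
            )
        ids[base] = met.id
    return ids


def install_biomass(
    model: MetabolicModel, spec: BiomassSpec, log: list | None = None
) -> MetabolicModel:
    """Install (or replace) the biomass reaction and make it the objective.

    The reaction consumes the components and ``gam`` ATP + ``gam`` water and
    produces ``gam`` ADP, phosphate and protons.  With ``gam`` = 0 no ATP
    terms are added.
    """
    missing = [m for m in spec.components if m not in model.metabolites]
    if missing:
        raise ModelError(f"biomass components absent from model: {sorted(missing)}")
    stoich: dict[str, Fraction] = {m: -abs(c) for m, c in spec.components.items()}
    if spec.gam > 0:
        gam = Fraction(spec.gam).limit_denominator(10**6)
        species = _energy_species(model, spec.compartment)
        for base, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            mid = species[base]
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * gam
    if BIOMASS_ID in model.reactions:
        before = dict(model.reactions[BIOMASS_ID].stoichiometry)
        model.remove_reaction(BIOMASS_ID)
    else:
        before = None
    rxn = Reaction(
        id=BIOMASS_ID,
        name="biomass",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=math.inf,
        flags={FLAG_BIOMASS},
    )
    model.add_reaction(rxn)
    model.biomass_reaction_id = BIOMASS_ID
    if log is not None:
        log.append(
            {
                "op": "install_biomass",
                "gam": spec.gam,
                "before": _stoich_str(before),
                "after": _stoich_str(stoich),
            }
        )
    return model


def install_medium(
    model: MetabolicModel, spec: MediumSpec, log: list | None = None
) -> MetabolicModel:
    """Set exchange uptake bounds per the medium; close all other uptakes.

    Secretion is governed by ``model.allowed_secretions``: the exchange of an
    allowed metabolite opens for outflow, every other exchange closes.
    Exchanges missing for a medium entry are created.  Idempotent.
    """
    new_medium: dict[str, float] = {}
    for met_id, rate in spec.uptakes.items():
        met = model.metabolites.get(met_id)
        if met is None:
            raise ModelError(f"medium metabolite {met_id!r} not in model")
        ex = model.exchange_for(met_id)
        if ex is None:
            ex = Reaction(
                id=f"EX_{met_id}",
                name=f"{met.name} exchange",
                stoichiometry={met_id: Fraction(-1)},
                lower_bound=0.0,
                upper_bound=0.0,
                flags={"exchange"},
            )
            model.add_reaction(ex)
        new_medium[ex.id] = float(rate)
    for ex in model.exchanges():
        ex.lower_bound = -new_medium.get(ex.id, 0.0)
        (met_id,) = ex.stoichiometry
        ex.upper_bound = math.inf if met_id in model.allowed_secretions else 0.0
    model.medium = new_medium
    if log is not None:
        log.append(
            {"op": "install_medium", "description": spec.description,
             "uptakes": dict(spec.uptakes)}
        )
    return model


def _redox_couples(model: MetabolicModel, rxn: Reaction):
    """(reactant, product) pairs where the product is the reactant plus 2 H
    (same charge shift), i.e. a reduction happening in the reaction."""
    reactants = [m for m, c in rxn.stoichiometry.items() if c < 0]
    products = [m for m, c in rxn.stoichiometry.items() if c > 0]
    couples = []
    for r in reactants:
        for p in products:
            mr, mp = model.metabolites[r], model.metabolites[p]
            if mr.formula is None or mp.formula is None:
                continue
            if mr.charge is None or mp.charge is None:
                continue
            if (
                mr.formula.without("H") == mp.formula.without("H")
                and mp.formula.get("H") - mr.formula.get("H") == 2
                and abs(rxn.stoichiometry[r]) == rxn.stoichiometry[p]
            ):
                couples.append((r, p))
    return couples


def fix_quinone_coupled_enzyme(
    model: MetabolicModel,
    reaction_id: str,
    quinone_id: str,
    quinol_id: str,
    log: list | None = None,
) -> MetabolicModel:
    """Re-wire an enzyme to the inner mitochondrial membrane.

    The reaction's electron-acceptor couple (the reactant/product pair that
    gains 2 H) is replaced by the mitochondrial quinone/quinol couple; all
    remaining participants are relocated to the intermembrane space ``i``.
    Mass/charge balance must be preserved, otherwise the model is left
    untouched and an error raised.  Idempotent.
    """
    rxn = model.reactions.get(reaction_id)
    if rxn is None:
        raise ModelError(f"reaction {reaction_id!r} not in model")
    for mid in (quinone_id, quinol_id):
        met = model.metabolites.get(mid)
        if met is None:
            raise ModelError(f"quinone-pool species {mid!r} not in model")
        if met.compartment != "m":
            raise ModelError(f"quinone-pool species {mid!r} must be mitochondrial")

    if quinone_id in rxn.stoichiometry and quinol_id in rxn.stoichiometry:
        others = [
            m for m in rxn.stoichiometry if m not in (quinone_id, quinol_id)
        ]
        if all(model.metabolites[m].compartment == "i" for m in others):
            return model  # already fixed

    couples = _redox_couples(model, rxn)
    acceptors = [
        (r, p) for r, p in couples if r not in (quinone_id, quinol_id)
    ]
    if len(acceptors) != 1:
        # ambiguity: pick the couple that is NOT the quinone pool and whose
        # members participate with coefficient matching each other; if still
        # ambiguous, refuse
        raise ModelError(
            f"cannot identify a unique electron-acceptor couple in "
            f"{reaction_id!r} (found {acceptors})"
        )
    old_q, old_qh2 = acceptors[0]
    before = dict(rxn.stoichiometry)
    coeff = rxn.stoichiometry[old_qh2]

    new_stoich: dict[str, Fraction] = {}
    for mid, c in rxn.stoichiometry.items():
        if mid == old_q:
            new_stoich[quinone_id] = c
        elif mid == old_qh2:
            new_stoich[quinol_id] = c
        else:
            inst = model.instantiate(model.metabolites[mid], "i")
            new_stoich[inst.id] = c
    rxn.stoichiometry = new_stoich

    imbalanced = [
        e for e in check_balance(model)
        if e.reaction_id == reaction_id and not e.skipped
    ]
    if imbalanced:
        rxn.stoichiometry = before
        e = imbalanced[0]
        raise ModelError(
            f"replacing the acceptor couple in {reaction_id!r} with "
            f"({quinone_id}, {quinol_id}) breaks balance: "
            f"{ {k: str(v) for k, v in e.element_imbalance.items()} }, "
            f"charge {e.charge_imbalance}"
        )
    model.remove_orphan_metabolites()
    if log is not None:
        log.append(
            {
                "op": "fix_quinone_coupled_enzyme",
                "reaction": reaction_id,
                "before": _stoich_str(before),
                "after": _stoich_str(new_stoich),
            }
        )
    return model


def add_intermembrane_shuttle(
    model: MetabolicModel, metabolite_id: str, log: list | None = None
) -> MetabolicModel:
    """Add a reversible, gene-less technical transporter c <-> i for one
    metabolite (outer-membrane permeability).  Idempotent."""
    met = model.metabolites.get(metabolite_id)
    if met is None:
        raise ModelError(f"metabolite {metabolite_id!r} not in model")
    if met.compartment != "c":
        raise ModelError(f"{metabolite_id!r} is not cytosolic")
    inst = model.instantiate(met, "i")
    target = {met.id: Fraction(-1), inst.id: Fraction(1)}
    for rxn in model.reactions.values():
        if FLAG_TRANSPORTER in rxn.flags and (
            rxn.stoichiometry == target
            or rxn.stoichiometry == {m: -c for m, c in target.items()}
        ):
            return model
    rxn = Reaction(
        id=f"{met.base_id().upper().replace('__', '_')}tci",
        name=f"{met.name} shuttle c<->i",
        stoichiometry=target,
        lower_bound=-math.inf,
        upper_bound=math.inf,
        flags={FLAG_TRANSPORTER},
    )
    model.add_reaction(rxn)
    if log is not None:
        log.append(
            {"op": "add_intermembrane_shuttle", "metabolite": metabolite_id,
             "reaction": rxn.id, "after": _stoich_str(rxn.stoichiometry)}
        )
    return model


def _stoich_str(stoich) -> dict | None:
    if stoich is None:
        return None
    return {m: str(c) for m, c in stoich.items()}
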