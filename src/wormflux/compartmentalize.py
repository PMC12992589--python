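"""Transfer compartment assignments from a template model onto a flat source
model, and graft the template's mitochondrion/cytosol transporters.

The flat source keeps most chemistry in the cytosol; reactions that map onto
a template reaction adopt the template's compartment, reactions the source
already designates as mitochondrial keep their own compartments, manual
assignments override everything, and the rest stays cytosolic (reported as
unresolved).  Template reactions spanning cytosol *and* mitochondrion are
transporters: they are not relocation targets but are grafted as new
reactions wherever all their transported species exist in the source
namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .core import (
    FLAG_BIOMASS,
    FLAG_DEMAND,
    FLAG_EXCHANGE,
    FLAG_MITO_DESIGNATED,
    FLAG_TRANSPORTER,
    MetabolicModel,
    ModelError,
    Reaction,
)
from .xref import MetaboliteMatch, ReactionMatch

__all__ = [
    "CompartmentPlan",
    "PlanEntry",
    "plan_compartments",
    "apply_compartment_plan",
    "graft_transporters",
    "read_manual_assignments",
]

ORIGIN_TEMPLATE = "template_transfer"
ORIGIN_DESIGNATED = "source_designation"
ORIGIN_MANUAL = "manual"


@dataclass
class PlanEntry:
    compartment: str  # target compartment for the reaction's cytosolic species
    origin: str


@dataclass
class CompartmentPlan:
    entries: dict[str, PlanEntry] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": rid, "compartment_id": e.compartment, "origin": e.origin}
            for rid, e in sorted(self.entries.items())
        ]
        rows += [
            {"reaction_id": rid, "compartment_id": "c", "origin": "unresolved"}
            for rid in self.unresolved
        ]
        return pd.DataFrame(rows)


def read_manual_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"reaction_id", "compartment_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"manual table {path} needs columns {sorted(required)}")
    return df


def plan_compartments(
    source: MetabolicModel,
    template: MetabolicModel,
    rxn_matches: list[ReactionMatch],
    manual: pd.DataFrame | None = None,
) -> CompartmentPlan:
    """Decide a target compartment for every source reaction.

    Matched, non-mitochondrially-designated reactions adopt the compartment
    of their template counterpart; designated reactions keep their own;
    manual entries override template transfers; everything else stays
    cytosolic and is listed as unresolved.  Template counterparts spanning
    {c, m} are transporters and yield no relocation.
    """
    match_by_source = {m.source_reaction_id: m for m in rxn_matches if m.mapped}
    plan = CompartmentPlan()
    for rxn_id in sorted(source.reactions):
        rxn = source.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS}:
            continue
        if FLAG_MITO_DESIGNATED in rxn.flags:
            comps = sorted(source.compartments_of(rxn))
            plan.entries[rxn_id] = PlanEntry("+".join(comps), ORIGIN_DESIGNATED)
            continue
        match = match_by_source.get(rxn_id)
        if match is not None:
            tmpl_rxn = template.reactions[match.template_reaction_id]
            comps = {
                c for c in template.compartments_of(tmpl_rxn) if c != "e"
            }
            if comps == {"c", "m"}:
                # transporter transfer, handled by graft_transporters
                plan.unresolved.append(rxn_id)
                continue
            if len(comps) == 1:
                plan.entries[rxn_id] = PlanEntry(comps.pop(), ORIGIN_TEMPLATE)
                continue
        plan.unresolved.append(rxn_id)

    if manual is not None:
        for row in manual.itertuples(index=False):
            rid, comp = str(row.reaction_id), str(row.compartment_id)
            if rid not in source.reactions:
                raise ModelError(f"manual assignment for unknown reaction {rid!r}")
            if comp not in set(source.compartments) | set(template.compartments):
                raise ModelError(f"manual assignment to unknown compartment {comp!r}")
            if rid in plan.entries and plan.entries[rid].origin == ORIGIN_DESIGNATED:
                # source designation is authoritative; record manual only for
                # reactions the designation does not already pin down
                continue
            plan.entries[rid] = PlanEntry(comp, ORIGIN_MANUAL)
            if rid in plan.unresolved:
                plan.unresolved.remove(rid)
    return plan


def apply_compartment_plan(
    source: MetabolicModel, plan: CompartmentPlan
) -> MetabolicModel:
    """Relocate planned reactions, creating compartment-specific metabolite
    instances on demand.  Designated (multi-compartment) entries are left in
    place; only cytosolic species of a relocated reaction move.  Idempotent;
    the balance report is unchanged (relocation copies formula and charge).
    """
    model = source.copy()
    for rxn_id, entry in plan.entries.items():
        if entry.origin == ORIGIN_DESIGNATED or "+" in entry.compartment:
            continue
        target = entry.compartment
        if target == "c":
            continue
        if target not in model.compartments:
            model.compartments[target] = target
        rxn = model.reactions[rxn_id]
        new_stoich: dict[str, Fraction] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.compartment == "c":
                inst = model.instantiate(met, target)
                new_stoich[inst.id] = new_stoich.get(inst.id, Fraction(0)) + coeff
            else:
                new_stoich[met_id] = new_stoich.get(met_id, Fraction(0)) + coeff
        rxn.stoichiometry = {m: c for m, c in new_stoich.items() if c != 0}
    model.remove_orphan_metabolites()
    return model


def _compartment_key(model: MetabolicModel, rxn: Reaction):
    agg: dict[tuple[str, str], Fraction] = {}
    for met_id, coeff in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        k = (met.base_id(), met.compartment)
        agg[k] = agg.get(k, Fraction(0)) + coeff
    return frozenset((k, c) for k, c in agg.items() if c != 0)


def graft_transporters(
    source: MetabolicModel,
    template: MetabolicModel,
    met_matches: list[MetaboliteMatch],
) -> tuple[MetabolicModel, list[str]]:
    """Copy the template's c<->m transporters into the source namespace.

    A template reaction spanning exactly cytosol and mitochondrion is grafted
    when each of its non-proton species has a selected verified match whose
    source-side species exists in the source model.  The graft keeps the
    template stoichiometry and bounds, instantiates source species in the
    needed compartments, and is skipped when an equivalent reaction (same
    compartment-aware stoichiometry, either direction) already exists —
    grafting twice changes nothing.
    """
    model = source.copy()
    inverse: dict[str, str] = {}
    for m in met_matches:
        if m.selected:
            inverse[m.template_metabolite_id] = m.source_metabolite_id

    source_bases = {met.base_id() for met in model.metabolites.values()}
    proton_base = None
    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        if met.is_free_proton:
            proton_base = met.base_id()
            break

    existing = {_compartment_key(model, r) for r in model.reactions.values()}
    existing |= {
        frozenset((k, -c) for k, c in key) for key in existing
    }

    added: list[str] = []
    for rxn_id in sorted(template.reactions):
        rxn = template.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS}:
            continue
        comps = template.compartments_of(rxn)
        if comps != {"c", "m"}:
            continue
        translated: dict[tuple[str, str], Fraction] = {}
        ok = True
        for met_id, coeff in rxn.stoichiometry.items():
            met = template.metabolites[met_id]
            if met.is_free_proton:
                if proton_base is None:
                    ok = False
                    break
                src_base = proton_base
            else:
                src_base = inverse.get(met.base_id())
                if src_base is None or src_base not in source_bases:
                    ok = False
                    break
            k = (src_base, met.compartment)
            translated[k] = translated.get(k, Fraction(0)) + coeff
        if not ok:
            continue
        key = frozenset((k, c) for k, c in translated.items() if c != 0)
        if key in existing:
            continue
        new_id = rxn_id if rxn_id not in model.reactions else f"{rxn_id}_graft"
        stoich: dict[str, Fraction] = {}
        for (base, comp), coeff in translated.items():
            if comp not in model.compartments:
                model.compartments[comp] = comp
            inst = model.find_metabolite(base, comp)
            if inst is None:
                proto = next(
                    met
                    for met in sorted(model.metabolites.values(), key=lambda m: m.id)
                    if met.base_id() == base
                )
                inst = model.instantiate(proto, comp)
            stoich[inst.id] = coeff
        model.add_reaction(
            Reaction(
                id=new_id,
                name=rxn.name or new_id,
                stoichiometry=stoich,
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                flags={FLAG_TRANSPORTER},
            )
        )
        existing.add(key)
        existing.add(frozenset((k, -c) for k, c in key))
        added.append(new_id)
    return model, added
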