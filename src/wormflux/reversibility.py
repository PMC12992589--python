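"""Reversibility and transporter-mechanism curation rules.

Four rule families raise the thermodynamic realism of a drafted network
without any explicit free-energy computation:

* decarboxylases become irreversible toward CO2 release (reverse operation
  would be uncoupled CO2 fixation, which is unrealistic without an
  ATP-driven carboxylating ligase, EC 6.4.1.-, which is exempt);
* isomerases (EC 5.-) become reversible — isomerizations are close to
  equilibrium;
* named hydrolases are clamped to the hydrolysis direction to break free
  ATP-regeneration loops;
* mitochondrial uniporters for phosphate/pyruvate-style cargo become proton
  symporters, the canonical inner-membrane mechanism.

The "irreversible" direction is always determined from the stoichiometry
(which side CO2 or free phosphate appears on), never from the stored writing
direction, which is arbitrary in database exports.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import pandas as pd

from .core import (
    FLAG_BIOMASS,
    FLAG_DEMAND,
    FLAG_EXCHANGE,
    FLAG_TRANSPORTER,
    MetabolicModel,
    ModelError,
    Reaction,
    ids_equivalent,
)

__all__ = [
    "make_decarboxylases_irreversible",
    "make_isomerases_reversible",
    "fix_energy_leaks",
    "convert_to_proton_symport",
    "apply_rules",
    "read_rules_table",
]

logger = logging.getLogger(__name__)


def _is_formula(met, counts: dict[str, int], charge: int) -> bool:
    return (
        met.formula is not None
        and met.charge == charge
        and dict(met.formula.items()) == counts
    )


def _net_coefficient(model: MetabolicModel, rxn: Reaction, counts, charge) -> Fraction:
    total = Fraction(0)
    for met_id, coeff in rxn.stoichiometry.items():
        if _is_formula(model.metabolites[met_id], counts, charge):
            total += coeff
    return total


def _has_energy_coupling(model: MetabolicModel, rxn: Reaction) -> bool:
    """Any participant carrying two or more phosphorus atoms (nucleotide
    di-/triphosphates, NAD(P), CoA): the reaction is energetically coupled
    and not a plain decarboxylase."""
    for met_id in rxn.stoichiometry:
        met = model.metabolites[met_id]
        if met.formula is not None and met.formula.get("P") >= 2:
            return True
    return False


def _clamp_to_direction(rxn: Reaction, forward: bool) -> bool:
    """Restrict bounds to one direction; returns True if bounds changed."""
    old = (rxn.lower_bound, rxn.upper_bound)
    if forward:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    else:
        rxn.upper_bound = min(rxn.upper_bound, 0.0)
    return (rxn.lower_bound, rxn.upper_bound) != old


def make_decarboxylases_irreversible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[str]]:
    """Clamp decarboxylases to the CO2-releasing direction.

    A reaction qualifies through its EC class (4.1.1.-) or, lacking EC data,
    through its stoichiometry: it is reversible, releases free CO2 in one
    direction, and has no energy coupling.  Carboxylating ligases
    (EC 6.4.1.-) and transport/boundary reactions are never touched.
    Idempotent; returns the ids whose bounds changed.
    """
    co2 = ({"C": 1, "O": 2}, 0)
    affected = []
    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS, FLAG_TRANSPORTER}:
            continue
        if any(ec.startswith("6.4.1") for ec in rxn.ec_numbers):
            continue
        if not rxn.reversible:
            continue  # direction already decided; nothing to prevent
        net_co2 = _net_coefficient(model, rxn, *co2)
        if net_co2 == 0:
            continue
        is_ec_decarb = any(ec.startswith("4.1.1") for ec in rxn.ec_numbers)
        if not is_ec_decarb and _has_energy_coupling(model, rxn):
            continue
        if not is_ec_decarb and not rxn.ec_numbers:
            pass  # stoichiometric fallback: reversible CO2 release, uncoupled
        elif not is_ec_decarb:
            continue  # EC known and not a decarboxylase
        if _clamp_to_direction(rxn, forward=net_co2 > 0):
            affected.append(rxn_id)
    return model, affected


def make_isomerases_reversible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[str]]:
    """Give every EC 5.- reaction symmetric bounds.  Idempotent."""
    affected = []
    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        if not any(ec.startswith("5.") for ec in rxn.ec_numbers):
            continue
        magnitude = max(abs(rxn.lower_bound), abs(rxn.upper_bound))
        if magnitude == 0:
            continue
        new = (-magnitude, magnitude)
        if (rxn.lower_bound, rxn.upper_bound) != new:
            rxn.lower_bound, rxn.upper_bound = new
            affected.append(rxn_id)
    return model, affected


def fix_energy_leaks(
    model: MetabolicModel, reaction_ids: list[str]
) -> MetabolicModel:
    """Clamp the listed hydrolases to the hydrolysis direction (the side that
    releases free phosphate), breaking free ATP-regeneration loops.

    Identifiers are matched after unescaping, treating hyphens and
    underscores as interchangeable.  Missing ids log a warning and leave the
    model unchanged.
    """
    phosphate = ({"H": 1, "O": 4, "P": 1}, -2)
    for wanted in reaction_ids:
        hits = [r for r in model.reactions if ids_equivalent(r, wanted)]
        if not hits:
            logger.warning("energy-leak rule: reaction %r not found", wanted)
            continue
        for rxn_id in hits:
            rxn = model.reactions[rxn_id]
            net_pi = _net_coefficient(model, rxn, *phosphate)
            if net_pi == 0:
                logger.warning(
                    "energy-leak rule: %r releases no free phosphate", rxn_id
                )
                continue
            _clamp_to_direction(rxn, forward=net_pi > 0)
    return model


def convert_to_proton_symport(
    model: MetabolicModel, transporter_ids: list[str]
) -> MetabolicModel:
    """Turn c<->m uniporters into proton symporters.

    The transporter must move exactly one non-proton cargo species between
    cytosol and mitochondrion; one proton per cargo molecule is added,
    co-moving in the cargo direction.  Mass and charge balance are preserved
    (the proton appears on both sides).  Idempotent.
    """
    for wanted in transporter_ids:
        hits = [r for r in model.reactions if ids_equivalent(r, wanted)]
        if not hits:
            logger.warning("symport rule: transporter %r not found", wanted)
            continue
        for rxn_id in hits:
            rxn = model.reactions[rxn_id]
            cargo: dict[str, dict[str, Fraction]] = {}
            protons: dict[str, Fraction] = {}
            for met_id, coeff in rxn.stoichiometry.items():
                met = model.metabolites[met_id]
                if met.is_free_proton:
                    protons[met.compartment] = coeff
                    continue
                cargo.setdefault(met.base_id(), {})[met.compartment] = coeff
            moved = {
                base: comps
                for base, comps in cargo.items()
                if set(comps) == {"c", "m"} and sum(comps.values()) == 0
            }
            if len(moved) != 1:
                raise ModelError(
                    f"transporter {rxn_id!r} must move exactly one non-proton "
                    f"species between c and m (found {sorted(moved) or 'none'})"
                )
            (base,) = moved
            comps = moved[base]
            if protons and protons.get("c") == comps["c"] and \
                    protons.get("m") == comps["m"]:
                continue  # already a symporter with matching direction
            proton_proto = next(
                (
                    met
                    for met in sorted(model.metabolites.values(), key=lambda m: m.id)
                    if met.is_free_proton
                ),
                None,
            )
            if proton_proto is None:
                raise ModelError("model has no free-proton species")
            for comp, coeff in comps.items():
                inst = model.instantiate(proton_proto, comp)
                rxn.stoichiometry[inst.id] = (
                    rxn.stoichiometry.get(inst.id, Fraction(0)) + coeff
                )
            rxn.stoichiometry = {
                m: c for m, c in rxn.stoichiometry.items() if c != 0
            }
    return model


# --- declarative rules file --------------------------------------------------


def read_rules_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"selector_type", "selector_value", "action"}
    if not required.issubset(df.columns):
        raise ValueError(f"rules table {path} needs columns {sorted(required)}")
    return df


def apply_rules(
    model: MetabolicModel, rules: pd.DataFrame
) -> tuple[MetabolicModel, pd.DataFrame]:
    """Apply a declarative rules table; returns the refinement log
    (reaction_id, old_bounds, new_bounds, rule)."""
    log_rows = []

    def snapshot():
        return {r: (x.lower_bound, x.upper_bound) for r, x in model.reactions.items()}

    for row in rules.itertuples(index=False):
        before = snapshot()
        rule_name = f"{row.selector_type}:{row.selector_value}:{row.action}"
        ids = [s for s in str(row.selector_value).split(";") if s]
        if row.action == "make_irreversible_forward":
            if row.selector_type == "reaction_id_list":
                fix_energy_leaks(model, ids)
            elif row.selector_type == "stoichiometric_pattern" and \
                    row.selector_value == "decarboxylase":
                make_decarboxylases_irreversible(model)
            elif row.selector_type == "ec_prefix":
                for rxn in model.reactions.values():
                    if any(ec.startswith(str(row.selector_value))
                           for ec in rxn.ec_numbers):
                        _clamp_to_direction(rxn, forward=True)
            else:
                raise ValueError(f"unsupported rule {rule_name!r}")
        elif row.action == "make_reversible":
            if row.selector_type == "ec_prefix" and \
                    str(row.selector_value).startswith("5"):
                make_isomerases_reversible(model)
            else:
                for rxn_id in ids:
                    hits = [r for r in model.reactions if ids_equivalent(r, rxn_id)]
                    if not hits:
                        logger.warning("rule %s: %r not found", rule_name, rxn_id)
                    for hit in hits:
                        rxn = model.reactions[hit]
                        magnitude = max(abs(rxn.lower_bound), abs(rxn.upper_bound))
                        rxn.lower_bound, rxn.upper_bound = -magnitude, magnitude
        elif row.action == "proton_symport":
            convert_to_proton_symport(model, ids)
        else:
            raise ValueError(f"unknown action {row.action!r}")
        after = snapshot()
        for rid in sorted(before):
            if before[rid] != after[rid]:
                log_rows.append(
                    {
                        "reaction_id": rid,
                        "old_bounds": str(before[rid]),
                        "new_bounds": str(after[rid]),
                        "rule": rule_name,
                    }
                )
    return model, pd.DataFrame(
        log_rows, columns=["reaction_id", "old_bounds", "new_bounds", "rule"]
    )


def standard_refinement(
    model: MetabolicModel,
    energy_leak_ids: list[str] = ("RXN_10862", "RXN-14218"),
    symporter_ids: list[str] = ("PYRt2m", "PIt2m"),
) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """The standard post-reconstruction battery in its canonical order."""
    _, decarb = make_decarboxylases_irreversible(model)
    _, isom = make_isomerases_reversible(model)
    fix_energy_leaks(model, list(energy_leak_ids))
    convert_to_proton_symport(model, list(symporter_ids))
    return model, {"decarboxylases": decarb, "isomerases": isom}
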