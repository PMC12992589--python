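"""Internal model representation, balance validation and structural pruning.

The in-memory containers deliberately stay close to the SBML-FBC data model
(species with formula/charge/compartment, reactions with rational stoichiometry
and flux bounds, a flux objective) while adding the bookkeeping this toolkit
needs: origin flags on reactions, namespace-qualified cross-references on
metabolites, an explicit medium (exchange uptake caps) and a secretion policy.

Stoichiometric coefficients are held as exact :class:`fractions.Fraction`
values so that curation steps and reaction-identity comparisons never suffer
from float drift; they are serialized as decimal doubles.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "ElementFormula",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BalanceEntry",
    "check_balance",
    "prune_structurally_inoperative",
    "sanitize_id",
    "unsanitize_id",
    "ids_equivalent",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for strings that are not a valid elemental formula."""


class ElementFormula:
    """An elemental composition: a map from element symbol to a count >= 0.

    Absent elements are equivalent to count zero; comparison is element-wise.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | str | None = None):
        if counts is None:
            self._counts: dict[str, int] = {}
        elif isinstance(counts, str):
            self._counts = _parse_formula(counts)
        else:
            self._counts = {}
            for el, n in counts.items():
                n = int(n)
                if n < 0:
                    raise FormulaError(f"negative count for element {el}: {n}")
                if n:
                    self._counts[el] = n

    @classmethod
    def parse(cls, text: str) -> "ElementFormula":
        return cls(text)

    def get(self, element: str) -> int:
        return self._counts.get(element, 0)

    def items(self):
        return self._counts.items()

    def elements(self) -> set[str]:
        return set(self._counts)

    def without(self, element: str) -> "ElementFormula":
        """The same composition with one element dropped (e.g. H)."""
        return ElementFormula({e: n for e, n in self._counts.items() if e != element})

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElementFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self):
        return hash(frozenset(self._counts.items()))

    def __bool__(self):
        return bool(self._counts)

    def __str__(self) -> str:
        # Hill-ish ordering: C, H, then alphabetical — the convention SBML
        # chemicalFormula strings use in practice.
        parts = []
        for el in self._sorted_elements():
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self):
        return f"ElementFormula({str(self)!r})"

    def _sorted_elements(self):
        keys = sorted(self._counts)
        ordered = [el for el in ("C", "H") if el in self._counts]
        ordered += [el for el in keys if el not in ("C", "H")]
        return ordered


def _parse_formula(text: str) -> dict[str, int]:
    text = text.strip()
    if not text:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"invalid formula {text!r} near position {pos}")
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"invalid formula {text!r} near position {pos}")
    return {e: n for e, n in counts.items() if n}


# --- identifier sanitization -------------------------------------------------
#
# SBML SIds admit only [A-Za-z_][A-Za-z0-9_]*.  BioCyc-style identifiers such
# as "RXN-14218" or "TRANS-RXN-123B" contain characters outside that set.  A
# declared, reversible escape keeps the SBML file valid while letting the
# toolkit recover the original identifier: every invalid character c becomes
# "__<ord(c)>__", and an id starting with a digit gains the prefix "x_".

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_ESCAPE = re.compile(r"__(\d+)__")


def sanitize_id(raw: str) -> str:
    out = []
    for i, ch in enumerate(raw):
        if (ch.isalnum() and not (i == 0 and ch.isdigit())) or ch == "_":
            out.append(ch)
        else:
            # a leading digit is escaped too: "__51__PG" starts with '_',
            # which is a valid SId start
            out.append(f"__{ord(ch)}__")
    return "".join(out)


def unsanitize_id(sid: str) -> str:
    return _ESCAPE.sub(lambda m: chr(int(m.group(1))), sid)


def ids_equivalent(a: str, b: str) -> bool:
    """True if two identifiers agree after unescaping, treating '-' and '_'
    as interchangeable (database exports use both spellings)."""
    ua = unsanitize_id(a).replace("-", "_")
    ub = unsanitize_id(b).replace("-", "_")
    return ua == ub


# --- domain types ------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species instance in one compartment."""

    id: str
    name: str = ""
    formula: ElementFormula | None = None  # None = unknown, excluded from balance
    charge: int | None = None
    compartment: str = "c"
    xrefs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def is_free_proton(self) -> bool:
        """A free proton: formula exactly {H:1} and charge +1."""
        return (
            self.formula is not None
            and self.charge == 1
            and dict(self.formula.items()) == {"H": 1}
        )

    def base_id(self) -> str:
        """The compartment-free identifier stem (``glc__D_c`` -> ``glc__D``)."""
        suffix = f"_{self.compartment}"
        if self.id.endswith(suffix) and len(self.id) > len(suffix):
            return self.id[: -len(suffix)]
        return self.id

    def copy(self) -> "Metabolite":
        return copy.deepcopy(self)


# Reaction origin flags.
FLAG_MITO_DESIGNATED = "mitochondrial_designated"
FLAG_GAP_FILLED = "gap_filled"
FLAG_TRANSPORTER = "transporter"
FLAG_EXCHANGE = "exchange"
FLAG_DEMAND = "demand"
FLAG_BIOMASS = "biomass"

KNOWN_FLAGS = {
    FLAG_MITO_DESIGNATED,
    FLAG_GAP_FILLED,
    FLAG_TRANSPORTER,
    FLAG_EXCHANGE,
    FLAG_DEMAND,
    FLAG_BIOMASS,
}


@dataclass
class Reaction:
    """Stoichiometry over metabolite ids with flux bounds.

    Negative coefficients consume, positive produce.  Bounds are floats and
    may be +-inf; coefficients are exact rationals.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = -math.inf
    upper_bound: float = math.inf
    gene_association: str = ""
    flags: set[str] = field(default_factory=set)
    ec_numbers: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items()}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_boundary(self) -> bool:
        return bool(self.flags & {FLAG_EXCHANGE, FLAG_DEMAND})

    def metabolite_ids(self) -> list[str]:
        return list(self.stoichiometry)

    def copy(self) -> "Reaction":
        return copy.deepcopy(self)


class ModelError(ValueError):
    """Raised on violated model invariants."""


@dataclass
class MetabolicModel:
    """Compartments, metabolites, reactions, biomass objective and medium."""

    id: str = "model"
    compartments: dict[str, str] = field(default_factory=dict)  # id -> name
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None
    medium: dict[str, float] = field(default_factory=dict)  # exchange id -> max uptake
    allowed_secretions: set[str] = field(default_factory=set)  # metabolite ids

    # -- construction ---------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ModelError(
                f"metabolite {met.id!r} references unknown compartment "
                f"{met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ModelError(f"reaction {rxn.id!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelError(f"reaction {rxn.id!r} has lower_bound > upper_bound")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(f"reaction {rxn.id!r} references unknown metabolites {missing}")
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND} and len(rxn.stoichiometry) != 1:
            raise ModelError(f"boundary reaction {rxn.id!r} must have exactly one metabolite")
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]
        self.medium.pop(rxn_id, None)
        if self.biomass_reaction_id == rxn_id:
            self.biomass_reaction_id = None

    def remove_orphan_metabolites(self) -> list[str]:
        used: set[str] = set()
        for rxn in self.reactions.values():
            used.update(rxn.stoichiometry)
        orphans = [m for m in self.metabolites if m not in used]
        for m in orphans:
            del self.metabolites[m]
        return orphans

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- queries --------------------------------------------------------------

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if FLAG_EXCHANGE in r.flags]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        for rxn in self.reactions.values():
            if FLAG_EXCHANGE in rxn.flags and metabolite_id in rxn.stoichiometry:
                return rxn
        return None

    def reactions_of(self, metabolite_id: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if metabolite_id in r.stoichiometry]

    def compartments_of(self, rxn: Reaction) -> set[str]:
        return {self.metabolites[m].compartment for m in rxn.stoichiometry}

    def find_metabolite(self, base_id: str, compartment: str) -> Metabolite | None:
        """Locate the instance of a compartment-free stem in one compartment."""
        cand = self.metabolites.get(f"{base_id}_{compartment}")
        if cand is not None and cand.compartment == compartment:
            return cand
        for met in self.metabolites.values():
            if met.compartment == compartment and met.base_id() == base_id:
                return met
        return None

    def instantiate(self, proto: Metabolite, compartment: str) -> Metabolite:
        """Find or create the instance of ``proto``'s species in ``compartment``,
        copying formula, charge and xrefs."""
        existing = self.find_metabolite(proto.base_id(), compartment)
        if existing is not None:
            return existing
        if compartment not in self.compartments:
            self.compartments[compartment] = compartment
        inst = Metabolite(
            id=f"{proto.base_id()}_{compartment}",
            name=proto.name,
            formula=proto.formula,
            charge=proto.charge,
            compartment=compartment,
            xrefs=copy.deepcopy(proto.xrefs),
        )
        return self.add_metabolite(inst)

    # -- validation -----------------------------------------------------------

    def validate(self, require_biomass: bool = False) -> None:
        if not self.compartments:
            raise ModelError("model has no compartments")
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {met.id!r} in unknown compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ModelError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id!r} has lower_bound > upper_bound")
            for m in rxn.stoichiometry:
                if m not in self.metabolites:
                    raise ModelError(f"reaction {rxn.id!r} references unknown metabolite {m!r}")
        for ex_id in self.medium:
            rxn = self.reactions.get(ex_id)
            if rxn is None or FLAG_EXCHANGE not in rxn.flags:
                raise ModelError(f"medium entry {ex_id!r} is not an exchange reaction")
        if require_biomass:
            bm = self.reactions.get(self.biomass_reaction_id or "")
            if bm is None:
                raise ModelError("model has no biomass reaction")
            if not any(c < 0 for c in bm.stoichiometry.values()):
                raise ModelError("biomass reaction consumes no metabolite")


# --- mass/charge balance -----------------------------------------------------


@dataclass
class BalanceEntry:
    """One problematic reaction in a balance report."""

    reaction_id: str
    element_imbalance: dict[str, Fraction]
    charge_imbalance: Fraction | None
    skipped: bool = False  # True when a participant has unknown formula/charge


def check_balance(model: MetabolicModel) -> list[BalanceEntry]:
    """Mass/charge balance report, ordered by reaction id.

    Exchange, demand and biomass reactions are excluded (they are policy, not
    chemistry).  A reaction with a participant of unknown formula or charge is
    reported as ``skipped`` rather than judged.
    """
    report: list[BalanceEntry] = []
    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS}:
            continue
        element_sum: dict[str, Fraction] = {}
        charge_sum = Fraction(0)
        unknown = False
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.formula is None or met.charge is None:
                unknown = True
                break
            for el, n in met.formula.items():
                element_sum[el] = element_sum.get(el, Fraction(0)) + coeff * n
            charge_sum += coeff * met.charge
        if unknown:
            report.append(BalanceEntry(rxn_id, {}, None, skipped=True))
            continue
        element_sum = {el: v for el, v in element_sum.items() if v != 0}
        if element_sum or charge_sum != 0:
            report.append(BalanceEntry(rxn_id, element_sum, charge_sum))
    return report


def assert_balanced(model: MetabolicModel) -> None:
    """Raise :class:`ModelError` when any internal reaction is imbalanced."""
    bad = [e for e in check_balance(model) if not e.skipped]
    if bad:
        lines = ", ".join(
            f"{e.reaction_id} ({ {k: str(v) for k, v in e.element_imbalance.items()} },"
            f" charge {e.charge_imbalance})"
            for e in bad
        )
        raise ModelError(f"imbalanced reactions: {lines}")


# --- structural pruning ------------------------------------------------------


def _producers_consumers(model: MetabolicModel, active: set[str]):
    """Per metabolite: which active reactions can produce / consume it,
    considering reversibility.  Boundary reactions count on both sides of
    their metabolite as dictated by their bounds."""
    producers: dict[str, set[str]] = {m: set() for m in model.metabolites}
    consumers: dict[str, set[str]] = {m: set() for m in model.metabolites}
    for rxn_id in active:
        rxn = model.reactions[rxn_id]
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                if fwd:
                    producers[met_id].add(rxn_id)
                if rev:
                    consumers[met_id].add(rxn_id)
            elif coeff < 0:
                if fwd:
                    consumers[met_id].add(rxn_id)
                if rev:
                    producers[met_id].add(rxn_id)
    return producers, consumers


def prune_structurally_inoperative(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[str]]:
    """Iteratively remove reactions touching dead-end metabolites.

    A metabolite is a dead end when, among the still-active reactions, it can
    only be produced or only be consumed (reversibility and boundary reactions
    taken into account).  Removal iterates to a fixpoint; the fixpoint is
    independent of removal order because dead-endedness is monotone under
    reaction removal.  Returns a pruned copy and the removed ids (sorted).
    """
    pruned = model.copy()
    active = set(pruned.reactions)
    removed: set[str] = set()
    while True:
        producers, consumers = _producers_consumers(pruned, active)
        dead_mets = set()
        for met_id in pruned.metabolites:
            touching = producers[met_id] | consumers[met_id]
            if not touching:
                continue
            if not producers[met_id] or not consumers[met_id]:
                dead_mets.add(met_id)
        to_remove = {
            rxn_id
            for rxn_id in active
            if any(m in dead_mets for m in pruned.reactions[rxn_id].stoichiometry)
        }
        if not to_remove:
            break
        active -= to_remove
        removed |= to_remove
    for rxn_id in removed:
        pruned.remove_reaction(rxn_id)
    pruned.remove_orphan_metabolites()
    return pruned, sorted(removed)
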