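"""Shared chemistry for the synthetic fixture models.

All fixture species carry real elemental formulas and charges (protonation
states as at pH 7, BiGG-style), so every fixture reaction can be — and is —
checked for exact mass and charge balance at construction time.  The only
exceptions are declared placeholder species (nucleotide "tokens" standing in
for DNA/RNA macromolecule precursors) whose element counts are *derived* as
the residual of their declared synthesis reaction, which keeps those
reactions balanceable by construction.
"""

from __future__ import annotations

import math
from fractions import Fraction

from ..core import (
    BalanceEntry,
    ElementFormula,
    MetabolicModel,
    Metabolite,
    Reaction,
    check_balance,
)

INF = math.inf

#: base species id -> (formula, charge).  Protonation states at pH ~7.
FORMULAS: dict[str, tuple[str, int]] = {
    # sugars and glycolysis
    "glc__D": ("C6H12O6", 0),
    "glc__bD": ("C6H12O6", 0),  # beta anomer, same composition
    "f6p": ("C6H11O9P", -2),
    "fdp": ("C6H10O12P2", -4),
    "pg3": ("C3H4O7P", -3),
    "pyr": ("C3H3O3", -1),
    # nucleotides and energy carriers
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "gtp": ("C10H12N5O14P3", -4),
    "gdp": ("C10H12N5O11P2", -3),
    "dgdp": ("C10H12N5O9P2", -3),
    "dgmp": ("C10H12N5O6P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "coa": ("C21H32N7O16P3S", -4),
    "accoa": ("C23H34N7O17P3S", -4),
    # inorganics
    "pi": ("HO4P", -2),
    "h": ("H", 1),
    "h2o": ("H2O", 0),
    "o2": ("O2", 0),
    "co2": ("CO2", 0),
    "hco3": ("CHO3", -1),
    "nh4": ("H4N", 1),
    "so4": ("O4S", -2),
    "ppi": ("HO7P2", -3),
    # organic acids / fermentation products
    "lac__L": ("C3H5O3", -1),
    "ac": ("C2H3O2", -1),
    "succ": ("C4H4O4", -2),
    "ppa": ("C3H5O2", -1),
    "oaa": ("C4H2O5", -2),
    "akg": ("C5H4O5", -2),
    "mal__L": ("C4H4O5", -2),
    "fum": ("C4H2O4", -2),
    # amino acids (the 20 proteinogenic)
    "ala__L": ("C3H7NO2", 0),
    "arg__L": ("C6H15N4O2", 1),
    "asn__L": ("C4H8N2O3", 0),
    "asp__L": ("C4H6NO4", -1),
    "cys__L": ("C3H7NO2S", 0),
    "gln__L": ("C5H10N2O3", 0),
    "glu__L": ("C5H8NO4", -1),
    "gly": ("C2H5NO2", 0),
    "his__L": ("C6H9N3O2", 0),
    "ile__L": ("C6H13NO2", 0),
    "leu__L": ("C6H13NO2", 0),
    "lys__L": ("C6H15N2O2", 1),
    "met__L": ("C5H11NO2S", 0),
    "phe__L": ("C9H11NO2", 0),
    "pro__L": ("C5H9NO2", 0),
    "ser__L": ("C3H7NO3", 0),
    "thr__L": ("C4H9NO3", 0),
    "trp__L": ("C11H12N2O2", 0),
    "tyr__L": ("C9H11NO3", 0),
    "val__L": ("C5H11NO2", 0),
    # fatty acids
    "hdca": ("C16H31O2", -1),  # palmitate
    "ocdcea": ("C18H33O2", -1),  # oleate
    # amino sugars (chitin monomer catabolism)
    "acgam": ("C8H15NO6", 0),
    "acgam6p": ("C8H14NO9P", -2),
    "gam6p": ("C6H13NO8P", -1),
    # vitamins (transported tokens with real formulas)
    "thm": ("C12H17N4OS", 1),
    "ribflv": ("C17H20N4O6", 0),
    "pydxn": ("C8H11NO3", 0),
    "pnto__R": ("C9H16NO5", -1),
    "fol": ("C19H17N7O6", -2),
    "cbl1": ("C62H88CoN13O14P", 0),
    # pyrimidine biosynthesis (UMP fixture)
    "cbp": ("CH2NO5P", -2),
    "cbasp": ("C5H6N2O5", -2),
    "dhor__S": ("C5H5N2O4", -1),
    "orot": ("C5H3N2O4", -1),
    "prpp": ("C5H8O14P3", -5),
    "omp": ("C10H10N2O11P", -3),
    "ump": ("C9H11N2O9P", -2),
    "ura": ("C4H4N2O2", 0),
    "q": ("C9H10O2", 0),  # abstract quinone head group with short tail
    "qh2": ("C9H12O2", 0),
}

PROTEINOGENIC = [
    "ala__L", "arg__L", "asn__L", "asp__L", "cys__L", "gln__L", "glu__L",
    "gly", "his__L", "ile__L", "leu__L", "lys__L", "met__L", "phe__L",
    "pro__L", "ser__L", "thr__L", "trp__L", "tyr__L", "val__L",
]

#: amino acids essential for metazoans (fixture medium default)
METAZOAN_ESSENTIAL_AA = [
    "his__L", "ile__L", "leu__L", "lys__L", "met__L",
    "phe__L", "thr__L", "trp__L", "val__L",
]

VITAMIN_TOKENS = ["thm", "ribflv", "pydxn", "pnto__R", "fol", "cbl1"]

#: DNA / RNA macromolecule-precursor tokens (placeholder species)
NUCLEOTIDE_TOKENS = [
    "datp_tok", "dctp_tok", "dgtp_tok", "dttp_tok",
    "ratp_tok", "rctp_tok", "rgtp_tok", "rutp_tok",
]

COMPARTMENT_NAMES = {
    "c": "cytosol",
    "m": "mitochondrion",
    "i": "mitochondrial intermembrane space",
    "e": "extracellular",
}


class FixtureBuildError(RuntimeError):
    pass


class ModelBuilder:
    """Incrementally build a :class:`MetabolicModel`, asserting exact mass and
    charge balance of every non-boundary reaction as it is added."""

    def __init__(self, model_id: str, compartments: list[str]):
        self.model = MetabolicModel(
            id=model_id,
            compartments={c: COMPARTMENT_NAMES.get(c, c) for c in compartments},
        )
        self.extra_formulas: dict[str, tuple[ElementFormula, int]] = {}

    def define_species(self, base: str, formula: ElementFormula, charge: int) -> None:
        """Register a species absent from the shared table (e.g. a token with
        a derived placeholder composition)."""
        self.extra_formulas[base] = (formula, charge)

    def _lookup(self, base: str) -> tuple[ElementFormula | None, int | None]:
        if base in self.extra_formulas:
            f, q = self.extra_formulas[base]
            return f, q
        if base in FORMULAS:
            text, q = FORMULAS[base]
            return ElementFormula(text), q
        return None, None

    def met(self, base: str, comp: str, name: str = "") -> str:
        """Ensure the species instance ``<base>_<comp>`` exists; return its id."""
        mid = f"{base}_{comp}"
        if mid not in self.model.metabolites:
            formula, charge = self._lookup(base)
            self.model.add_metabolite(
                Metabolite(
                    id=mid,
                    name=name or base,
                    formula=formula,
                    charge=charge,
                    compartment=comp,
                    xrefs={"bigg.metabolite": [base]} if base in FORMULAS else {},
                )
            )
        return mid

    def rxn(
        self,
        rxn_id: str,
        stoich: dict[tuple[str, str], int | Fraction],
        lb: float = 0.0,
        ub: float = INF,
        flags: set[str] | None = None,
        ec: list[str] | None = None,
        gpr: str = "",
        name: str = "",
    ) -> Reaction:
        full = {self.met(base, comp): Fraction(c) for (base, comp), c in stoich.items()}
        reaction = Reaction(
            id=rxn_id,
            name=name or rxn_id,
            stoichiometry=full,
            lower_bound=lb,
            upper_bound=ub,
            flags=set(flags or ()),
            ec_numbers=list(ec or ()),
            gene_association=gpr,
        )
        self.model.add_reaction(reaction)
        self._assert_reaction_balanced(reaction)
        return reaction

    def exchange(self, base: str, uptake: float | None = None) -> Reaction:
        """Boundary exchange for the extracellular instance of ``base``.

        ``uptake`` opens the reverse (inflow) direction and records the cap in
        the model medium; secretion stays closed until the species is added to
        ``allowed_secretions`` (bounds are synchronised by the caller)."""
        mid = self.met(base, "e")
        rxn = Reaction(
            id=f"EX_{base}_e",
            name=f"{base} exchange",
            stoichiometry={mid: Fraction(-1)},
            lower_bound=-(uptake if uptake is not None else 0.0),
            upper_bound=0.0,
            flags={"exchange"},
        )
        self.model.add_reaction(rxn)
        if uptake is not None:
            self.model.medium[rxn.id] = float(uptake)
        return rxn

    def transport(self, base: str, comp_a: str, comp_b: str, lb: float = -INF) -> Reaction:
        return self.rxn(
            f"{base.upper()}t_{comp_a}{comp_b}",
            {(base, comp_a): -1, (base, comp_b): 1},
            lb=lb,
            ub=INF,
            flags={"transporter"},
        )

    def allow_secretion(self, base: str) -> None:
        mid = f"{base}_e"
        self.model.allowed_secretions.add(mid)
        ex = self.model.exchange_for(mid)
        if ex is not None:
            ex.upper_bound = INF

    def residual_formula(
        self,
        inputs: dict[str, int | Fraction],
        known_outputs: dict[str, int | Fraction],
    ) -> tuple[ElementFormula, int]:
        """Element counts and charge of the single unknown product of a lumped
        reaction, derived so the reaction balances exactly."""
        elements: dict[str, Fraction] = {}
        charge = Fraction(0)
        for side, sign in ((inputs, 1), (known_outputs, -1)):
            for base, coeff in side.items():
                formula, q = self._lookup(base)
                if formula is None or q is None:
                    raise FixtureBuildError(f"unknown species {base!r} in residual")
                for el, n in formula.items():
                    elements[el] = elements.get(el, Fraction(0)) + sign * Fraction(coeff) * n
                charge += sign * Fraction(coeff) * q
        counts = {}
        for el, v in elements.items():
            if v == 0:
                continue
            if v < 0 or v.denominator != 1:
                raise FixtureBuildError(
                    f"residual species would need {el} count {v}; adjust the lump"
                )
            counts[el] = int(v)
        if charge.denominator != 1:
            raise FixtureBuildError("residual species charge is fractional")
        return ElementFormula(counts), int(charge)

    def _assert_reaction_balanced(self, reaction: Reaction) -> None:
        if reaction.flags & {"exchange", "demand", "biomass"}:
            return
        probe = MetabolicModel(
            id="probe",
            compartments=dict(self.model.compartments),
            metabolites={
                m: self.model.metabolites[m] for m in reaction.stoichiometry
            },
        )
        probe.reactions[reaction.id] = reaction
        report = [e for e in check_balance(probe) if not e.skipped]
        if report:
            e: BalanceEntry = report[0]
            raise FixtureBuildError(
                f"fixture reaction {reaction.id} is imbalanced: "
                f"{ {k: str(v) for k, v in e.element_imbalance.items()} }, "
                f"charge {e.charge_imbalance}"
            )
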