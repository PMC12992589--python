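"""SBML Level 3 + FBC input/output and policy-table parsing.

SBML serialization is delegated to cobrapy (which wraps libsbml); this module
translates between cobra's containers and :class:`wormflux.core.MetabolicModel`.
Toolkit-specific bookkeeping that SBML-FBC has no slot for — reaction origin
flags and the original (unsanitized) identifiers — travels in SBML notes, so a
written file is self-contained and round-trips.

The medium and the secretion policy are *derived* state: on read they are
reconstructed from the exchange-reaction bounds (uptake = negative lower
bound, secretion allowed = positive upper bound), which is also how
:func:`wormflux.curation.install_medium` encodes them.
"""

from __future__ import annotations

import math
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .core import (
    FLAG_EXCHANGE,
    KNOWN_FLAGS,
    ElementFormula,
    FormulaError,
    MetabolicModel,
    Metabolite,
    Reaction,
    sanitize_id,
)

__all__ = [
    "read_model",
    "write_model",
    "read_medium_table",
    "read_secretion_table",
    "write_medium_table",
    "write_secretion_table",
]

_FLAGS_NOTE = "wormflux_flags"
_ORIG_ID_NOTE = "wormflux_id"


class SBMLReadError(ValueError):
    pass


def _to_cobra(model: MetabolicModel):
    import cobra

    model.validate()
    cm = cobra.Model(sanitize_id(model.id) or "model")
    cm.compartments = dict(model.compartments)
    # cobra's writer only emits compartments that species reference; keep the
    # full declared table in a model note so empty compartments round-trip
    cm.notes["wormflux_compartments"] = ";".join(
        f"{cid}={name}" for cid, name in sorted(model.compartments.items())
    )

    cmets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            sanitize_id(met.id),
            formula=str(met.formula) if met.formula is not None else None,
            name=met.name or met.id,
            charge=met.charge,
            compartment=met.compartment,
        )
        if met.xrefs:
            m.annotation = {ns: list(ids) for ns, ids in met.xrefs.items()}
        if sanitize_id(met.id) != met.id:
            m.notes[_ORIG_ID_NOTE] = met.id
        cmets[met.id] = m
    cm.add_metabolites(list(cmets.values()))

    crxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(sanitize_id(rxn.id), name=rxn.name or rxn.id)
        crxns.append(r)
    cm.add_reactions(crxns)
    for rxn, r in zip(model.reactions.values(), crxns):
        r.add_metabolites(
            {cmets[m]: float(c) for m, c in rxn.stoichiometry.items()}
        )
        r.lower_bound = float(rxn.lower_bound)
        r.upper_bound = float(rxn.upper_bound)
        if rxn.gene_association:
            r.gene_reaction_rule = rxn.gene_association
        if rxn.ec_numbers:
            ecs = list(rxn.ec_numbers)
            r.annotation["ec-code"] = ecs if len(ecs) > 1 else ecs[0]
        if rxn.flags:
            r.notes[_FLAGS_NOTE] = ";".join(sorted(rxn.flags))
        if sanitize_id(rxn.id) != rxn.id:
            r.notes[_ORIG_ID_NOTE] = rxn.id
    if model.biomass_reaction_id:
        cm.objective = cm.reactions.get_by_id(sanitize_id(model.biomass_reaction_id))
    return cm


def _coeff_to_fraction(value: float) -> Fraction:
    # SBML stores doubles; recover the tidy rational a human wrote
    # (1/2 serialized as 0.5 comes back as Fraction(1, 2)).
    return Fraction(value).limit_denominator(10**9)


def _from_cobra(cm, strict: bool = True) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    model.compartments = {cid: name or cid for cid, name in cm.compartments.items()}
    note = (cm.notes or {}).get("wormflux_compartments")
    if note:
        for item in str(note).split(";"):
            cid, _, name = item.partition("=")
            model.compartments.setdefault(cid, name or cid)
    if not model.compartments:
        # species may still carry compartment ids even if the listing is empty
        for m in cm.metabolites:
            if m.compartment:
                model.compartments.setdefault(m.compartment, m.compartment)

    id_map = {}
    for m in cm.metabolites:
        orig = m.notes.get(_ORIG_ID_NOTE, m.id)
        formula = None
        if m.formula:
            try:
                formula = ElementFormula(m.formula)
            except FormulaError:
                formula = None
        xrefs = {
            ns: (list(v) if isinstance(v, (list, tuple)) else [v])
            for ns, v in (m.annotation or {}).items()
            if ns != "sbo"
        }
        met = Metabolite(
            id=orig,
            name=m.name or orig,
            formula=formula,
            charge=int(m.charge) if m.charge is not None else None,
            compartment=m.compartment,
            xrefs=xrefs,
        )
        model.add_metabolite(met)
        id_map[m.id] = orig

    missing_bounds = [
        r.id for r in cm.reactions if r.lower_bound is None or r.upper_bound is None
    ]
    if missing_bounds and strict:
        raise SBMLReadError(f"reactions without FBC bounds: {missing_bounds}")

    objective_ids = {
        v.name for v in cm.objective.variables
    }  # forward/reverse variable names contain the reaction id

    for r in cm.reactions:
        orig = r.notes.get(_ORIG_ID_NOTE, r.id)
        flags = set()
        note = r.notes.get(_FLAGS_NOTE)
        if note:
            flags = {f for f in str(note).split(";") if f in KNOWN_FLAGS}
        if not flags and r.boundary:
            flags = {FLAG_EXCHANGE}
        ec = r.annotation.get("ec-code", [])
        if isinstance(ec, str):
            ec = [ec]
        rxn = Reaction(
            id=orig,
            name=r.name or orig,
            stoichiometry={
                id_map[m.id]: _coeff_to_fraction(c) for m, c in r.metabolites.items()
            },
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gene_association=r.gene_reaction_rule or "",
            flags=flags,
            ec_numbers=list(ec),
        )
        model.add_reaction(rxn)
        if r.id in objective_ids or r.objective_coefficient:
            model.biomass_reaction_id = orig

    # medium and secretion policy from exchange bounds
    for rxn in model.exchanges():
        if rxn.lower_bound < 0:
            model.medium[rxn.id] = -rxn.lower_bound
        if rxn.upper_bound > 0:
            (met_id,) = rxn.stoichiometry
            model.allowed_secretions.add(met_id)
    return model


def read_model(path: str | Path, dialect: str = "sbml_fbc") -> MetabolicModel:
    """Load an SBML Level 3 + FBC model file.

    Species formulas/charges are taken from the FBC attributes; MIRIAM-style
    annotations become per-namespace xref lists; identifiers written by this
    toolkit's escape scheme are restored verbatim.
    """
    if dialect != "sbml_fbc":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports the offending element in its message
        raise SBMLReadError(f"cannot parse SBML file {path}: {exc}") from exc
    return _from_cobra(cm)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Serialize to SBML Level 3 Version 1 with FBC v2.

    ``read_model(write_model(m))`` is structurally identical to ``m`` for any
    model that passes :meth:`MetabolicModel.validate`.  Rational coefficients
    are written as exact decimal doubles.
    """
    from cobra.io import write_sbml_model

    cm = _to_cobra(model)
    write_sbml_model(cm, str(path))


# --- policy tables -----------------------------------------------------------


def read_medium_table(path: str | Path) -> dict[str, float]:
    """TSV with columns ``exchange_reaction_id``, ``max_uptake``."""
    df = pd.read_csv(path, sep="\t", dtype={"exchange_reaction_id": str})
    required = {"exchange_reaction_id", "max_uptake"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"medium table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    medium = {}
    for row in df.itertuples(index=False):
        rate = float(row.max_uptake)
        if rate < 0 or math.isnan(rate):
            raise ValueError(
                f"negative or missing uptake for {row.exchange_reaction_id!r}"
            )
        medium[str(row.exchange_reaction_id)] = rate
    return medium


def write_medium_table(medium: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(medium.items()), columns=["exchange_reaction_id", "max_uptake"]
    ).to_csv(path, sep="\t", index=False)


def read_secretion_table(path: str | Path) -> set[str]:
    """TSV with a single ``metabolite_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "metabolite_id" not in df.columns:
        raise ValueError(f"secretion table {path} must have a metabolite_id column")
    return set(df["metabolite_id"].dropna())


def write_secretion_table(secretions: set[str], path: str | Path) -> None:
    pd.DataFrame(sorted(secretions), columns=["metabolite_id"]).to_csv(
        path, sep="\t", index=False
    )
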