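"""Cross-namespace identifier mapping with protonation-tolerant verification.

Two reference biochemistries (e.g. a BioCyc-derived flat model and a
BiGG-derived template) name the same metabolite differently *and* may store
it in different protonation states, hence with different formulas and
charges.  A candidate identifier pair is therefore chemically *verified*:
the match is accepted exactly when all non-hydrogen element counts agree and
the hydrogen-count difference equals the charge difference (a pure
protonation shift).  Candidate pairs come from an undirected cross-reference
graph whose edges carry provenance:

* ``direct_link`` — an explicit link between the two namespaces,
* ``bridge_table`` — both identifiers are members of the same entry of a
  bridging registry (MetaNetX-style),
* ``shared_third_party`` — both identifiers annotate the same identifier of
  a third namespace (KEGG-style),
* ``manual`` — a hand-curated assertion (highest priority).

Paths are never chased further than one intermediate third-party node:
transitive closure over noisy cross-references causes identifier drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import pandas as pd

from .core import (
    FLAG_BIOMASS,
    FLAG_DEMAND,
    FLAG_EXCHANGE,
    ElementFormula,
    MetabolicModel,
    Metabolite,
)

__all__ = [
    "CrossRefGraph",
    "MetaboliteMatch",
    "ReactionMatch",
    "protonation_compatible",
    "build_xref_graph",
    "match_metabolites",
    "match_reactions",
    "selected_matches",
    "read_link_table",
    "read_bridge_table",
]

PROVENANCE_PRIORITY = {
    "manual": 3,
    "direct_link": 2,
    "bridge_table": 1,
    "shared_third_party": 0,
}

STATUS_VERIFIED = "verified"
STATUS_REJECTED_FORMULA = "rejected_formula"
STATUS_REJECTED_CHARGE = "rejected_charge"
STATUS_UNVERIFIABLE = "unverifiable"


def protonation_compatible(
    formula_a: ElementFormula | None,
    charge_a: int | None,
    formula_b: ElementFormula | None,
    charge_b: int | None,
) -> tuple[bool, int | None]:
    """Are two (formula, charge) pairs the same species up to protonation?

    Compatible iff every non-H element count is equal and the H difference
    equals the charge difference.  Returns ``(compatible, proton_delta)``
    with ``proton_delta = H_b - H_a`` (0 for identical formulas); for
    unknown formulas or charges returns ``(False, None)`` — unknown species
    are never silently matched.
    """
    if formula_a is None or formula_b is None or charge_a is None or charge_b is None:
        return False, None
    if formula_a.without("H") != formula_b.without("H"):
        return False, None
    delta_h = formula_b.get("H") - formula_a.get("H")
    if delta_h != charge_b - charge_a:
        return False, None
    return True, delta_h


@dataclass
class CrossRefGraph:
    """Undirected identifier graph over (namespace, identifier) nodes."""

    source_ns: str
    template_ns: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, node_a, node_b, provenance: str) -> None:
        if provenance not in PROVENANCE_PRIORITY:
            raise ValueError(f"unknown provenance {provenance!r}")
        if node_a == node_b:
            return  # no self-edges
        if self.graph.has_edge(node_a, node_b):
            self.graph.edges[node_a, node_b]["provenance"].add(provenance)
        else:
            self.graph.add_edge(node_a, node_b, provenance={provenance})

    def candidate_template_ids(self, source_id: str) -> dict[str, set[str]]:
        """Template-namespace identifiers reachable from a source identifier,
        with the provenances supporting each (direct edges only; bridge and
        third-party paths were collapsed to edges at build time)."""
        node = (self.source_ns, source_id)
        found: dict[str, set[str]] = {}
        if node not in self.graph:
            return found
        for nbr in self.graph.neighbors(node):
            ns, ident = nbr
            if ns == self.template_ns:
                found.setdefault(ident, set()).update(
                    self.graph.edges[node, nbr]["provenance"]
                )
        return found


def read_link_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_ns", "source_id", "target_ns", "target_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"link table {path} needs columns {sorted(required)}")
    return df


def read_bridge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"bridge_ns", "bridge_id", "member_ns", "member_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"bridge table {path} needs columns {sorted(required)}")
    return df


def build_xref_graph(
    source_ns: str,
    template_ns: str,
    direct_links: pd.DataFrame | None = None,
    bridge_tables: list[pd.DataFrame] | None = None,
    third_party_annotations: dict[str, dict[str, dict[str, list[str]]]] | None = None,
) -> CrossRefGraph:
    """Assemble the cross-reference graph.

    ``direct_links``: columns source_ns, source_id, target_ns, target_id.
    ``bridge_tables``: columns bridge_ns, bridge_id, member_ns, member_id;
    all members of one bridge entry become pairwise ``bridge_table`` edges.
    ``third_party_annotations``: per namespace, per entity id, an
    xref mapping {third_ns: [ids]}; whenever a source-namespace and a
    template-namespace entity annotate the same third-party identifier a
    ``shared_third_party`` edge is added between them (and to the third-party
    node itself, keeping the one-intermediate path inspectable).

    Duplicate or contradictory rows are all kept — resolution happens at
    match time, chemically.  Deterministic for fixed input order.
    """
    g = CrossRefGraph(source_ns=source_ns, template_ns=template_ns)
    if direct_links is not None:
        for row in direct_links.itertuples(index=False):
            g.add_edge(
                (row.source_ns, row.source_id),
                (row.target_ns, row.target_id),
                "direct_link",
            )
    for table in bridge_tables or []:
        for (_, _), group in table.groupby(["bridge_ns", "bridge_id"], sort=False):
            members = [(r.member_ns, r.member_id) for r in group.itertuples(index=False)]
            for i, a in enumerate(members):
                for bnode in members[i + 1:]:
                    g.add_edge(a, bnode, "bridge_table")
    if third_party_annotations:
        # index: third-party node -> entities annotating it
        tp_index: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for ns, entities in third_party_annotations.items():
            for ent_id, xrefs in entities.items():
                for tp_ns, tp_ids in xrefs.items():
                    for tp_id in tp_ids:
                        tp_node = (tp_ns, tp_id)
                        g.add_edge((ns, ent_id), tp_node, "shared_third_party")
                        tp_index.setdefault(tp_node, []).append((ns, ent_id))
        for tp_node, entities in tp_index.items():
            sources = [e for e in entities if e[0] == source_ns]
            templates = [e for e in entities if e[0] == template_ns]
            for s in sources:
                for t in templates:
                    g.add_edge(s, t, "shared_third_party")
    return g


def model_annotations(model: MetabolicModel, namespace: str) -> dict[str, dict]:
    """Per-base-id xrefs of one model, keyed for build_xref_graph."""
    out: dict[str, dict[str, list[str]]] = {}
    for met in model.metabolites.values():
        base = met.base_id()
        if met.xrefs:
            merged = out.setdefault(base, {})
            for ns, ids in met.xrefs.items():
                merged.setdefault(ns, [])
                for i in ids:
                    if i not in merged[ns]:
                        merged[ns].append(i)
    return out


@dataclass
class MetaboliteMatch:
    """One candidate pairing of a source and a template species."""

    source_metabolite_id: str  # compartment-free base id in the source namespace
    template_metabolite_id: str | None
    provenance: str | None
    proton_delta: int | None  # template H count minus source H count
    status: str
    selected: bool = False


def _representative(model: MetabolicModel, base_id: str) -> Metabolite | None:
    instances = sorted(
        (m for m in model.metabolites.values() if m.base_id() == base_id),
        key=lambda m: m.id,
    )
    return instances[0] if instances else None


def match_metabolites(
    source: MetabolicModel,
    template: MetabolicModel,
    graph: CrossRefGraph,
    manual: pd.DataFrame | None = None,
) -> list[MetaboliteMatch]:
    """Chemically verified metabolite matching.

    For every source species (by compartment-free base id) the graph
    candidates are verified with :func:`protonation_compatible`; among
    verified candidates exactly one is selected by provenance priority
    manual > direct_link > bridge_table > shared_third_party, ties broken by
    lexicographic template id.  All candidates — verified, rejected and
    unverifiable — are reported; ambiguity is data, not an error.
    """
    g = graph
    if manual is not None and len(manual):
        g = CrossRefGraph(graph.source_ns, graph.template_ns, graph.graph.copy())
        for row in manual.itertuples(index=False):
            g.add_edge(
                (row.source_ns, row.source_id),
                (row.target_ns, row.target_id),
                "manual",
            )

    template_bases = sorted({m.base_id() for m in template.metabolites.values()})
    report: list[MetaboliteMatch] = []
    source_bases = sorted({m.base_id() for m in source.metabolites.values()})
    for src_base in source_bases:
        src_met = _representative(source, src_base)
        candidates = g.candidate_template_ids(src_base)
        records: list[MetaboliteMatch] = []
        for tmpl_base in sorted(candidates):
            if tmpl_base not in set(template_bases):
                continue
            provs = candidates[tmpl_base]
            provenance = max(provs, key=lambda p: PROVENANCE_PRIORITY[p])
            tmpl_met = _representative(template, tmpl_base)
            status, delta = _verify(src_met, tmpl_met)
            records.append(
                MetaboliteMatch(
                    source_metabolite_id=src_base,
                    template_metabolite_id=tmpl_base,
                    provenance=provenance,
                    proton_delta=delta,
                    status=status,
                )
            )
        verified = [r for r in records if r.status == STATUS_VERIFIED]
        if verified:
            best = min(
                verified,
                key=lambda r: (
                    -PROVENANCE_PRIORITY[r.provenance],
                    # lexicographically smallest id wins on equal provenance
                    r.template_metabolite_id,
                ),
            )
            best.selected = True
        if not records:
            records.append(
                MetaboliteMatch(src_base, None, None, None, STATUS_UNVERIFIABLE)
            )
        report.extend(records)
    return report


def _verify(src_met: Metabolite, tmpl_met: Metabolite) -> tuple[str, int | None]:
    if (
        src_met.formula is None
        or tmpl_met.formula is None
        or src_met.charge is None
        or tmpl_met.charge is None
    ):
        return STATUS_UNVERIFIABLE, None
    if src_met.formula.without("H") != tmpl_met.formula.without("H"):
        return STATUS_REJECTED_FORMULA, None
    ok, delta = protonation_compatible(
        src_met.formula, src_met.charge, tmpl_met.formula, tmpl_met.charge
    )
    if not ok:
        return STATUS_REJECTED_CHARGE, None
    return STATUS_VERIFIED, delta


def selected_matches(matches: list[MetaboliteMatch]) -> dict[str, str]:
    """source base id -> template base id, selected verified matches only."""
    return {
        m.source_metabolite_id: m.template_metabolite_id
        for m in matches
        if m.selected
    }


@dataclass
class ReactionMatch:
    """A source reaction mapped (or not) onto template reactions."""

    source_reaction_id: str
    template_reaction_id: str | None
    direction: str | None  # same | reversed
    proton_adjustment: dict[str, Fraction] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return self.template_reaction_id is not None

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1


def _stripped_key(
    model: MetabolicModel,
    stoich: dict[str, Fraction],
    translate: dict[str, str] | None = None,
):
    """Compartment-agnostic, proton-stripped (base id -> coefficient)
    multiset; None if a non-proton species cannot be translated."""
    agg: dict[str, Fraction] = {}
    for met_id, coeff in stoich.items():
        met = model.metabolites[met_id]
        if met.is_free_proton:
            continue
        base = met.base_id()
        if translate is not None:
            if base not in translate:
                return None
            base = translate[base]
        agg[base] = agg.get(base, Fraction(0)) + coeff
    agg = {b: c for b, c in agg.items() if c != 0}
    return frozenset(agg.items())


def _proton_by_compartment(model: MetabolicModel, stoich) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for met_id, coeff in stoich.items():
        met = model.metabolites[met_id]
        if met.is_free_proton:
            out[met.compartment] = out.get(met.compartment, Fraction(0)) + coeff
    return out


def match_reactions(
    source: MetabolicModel,
    template: MetabolicModel,
    met_matches: list[MetaboliteMatch],
) -> list[ReactionMatch]:
    """Map source reactions onto template reactions through the selected
    metabolite matches.

    A source reaction is mappable only if every non-proton participant has a
    selected verified match.  Both sides are compared as compartment-
    agnostic, free-proton-stripped coefficient multisets; equality means a
    match with the same direction, equality after negation a reversed match.
    Exchange/demand/biomass reactions never participate (policy, not
    chemistry).  All matching template reactions are recorded, ordered
    lexicographically; the first is the chosen one.
    """
    translate = selected_matches(met_matches)

    index: dict[frozenset, list[tuple[str, str]]] = {}
    for rxn_id in sorted(template.reactions):
        rxn = template.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS}:
            continue
        key = _stripped_key(template, rxn.stoichiometry)
        if key is None or not key:
            continue
        index.setdefault(key, []).append((rxn_id, "same"))
        neg = frozenset({b: -c for b, c in dict(key).items()}.items())
        index.setdefault(neg, []).append((rxn_id, "reversed"))

    report: list[ReactionMatch] = []
    for rxn_id in sorted(source.reactions):
        rxn = source.reactions[rxn_id]
        if rxn.flags & {FLAG_EXCHANGE, FLAG_DEMAND, FLAG_BIOMASS}:
            continue
        key = _stripped_key(source, rxn.stoichiometry, translate)
        if key is None or not key:
            report.append(ReactionMatch(rxn_id, None, None))
            continue
        hits = index.get(key, [])
        # one template reaction may appear with both directions (e.g. a
        # perfectly symmetric key); prefer 'same'
        seen: dict[str, str] = {}
        for tid, direction in hits:
            if tid not in seen or direction == "same":
                seen[tid] = direction
        ordered = sorted(seen)
        if not ordered:
            report.append(ReactionMatch(rxn_id, None, None))
            continue
        chosen = ordered[0]
        tmpl_rxn = template.reactions[chosen]
        tmpl_h = _proton_by_compartment(template, tmpl_rxn.stoichiometry)
        src_h = _proton_by_compartment(source, rxn.stoichiometry)
        adjustment = dict(tmpl_h)
        for comp, coeff in src_h.items():
            adjustment[comp] = adjustment.get(comp, Fraction(0)) - coeff
        adjustment = {c: v for c, v in adjustment.items() if v != 0}
        report.append(
            ReactionMatch(
                source_reaction_id=rxn_id,
                template_reaction_id=chosen,
                direction=seen[chosen],
                proton_adjustment=adjustment,
                candidates=ordered,
            )
        )
    return report


def matches_to_frame(matches: list[MetaboliteMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_metabolite_id": m.source_metabolite_id,
                "template_metabolite_id": m.template_metabolite_id,
                "provenance": m.provenance,
                "proton_delta": m.proton_delta,
                "status": m.status,
                "selected": m.selected,
            }
            for m in matches
        ]
    )


def reaction_matches_to_frame(matches: list[ReactionMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_reaction_id": m.source_reaction_id,
                "template_reaction_id": m.template_reaction_id,
                "direction": m.direction,
                "proton_adjustment": ";".join(
                    f"{c}:{v}" for c, v in sorted(m.proton_adjustment.items())
                ),
                "candidates": ";".join(m.candidates),
                "ambiguous": m.ambiguous,
            }
            for m in matches
        ]
    )
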