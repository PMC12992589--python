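"""Seeded metabolite/reaction mapping fixture.

Generates a paired source/template metabolite universe with synthetic
formulas, connects them through direct links, a bridge namespace and a
shared third-party namespace, and plants:

* protonation mismatches obeying the rule dH = dcharge (must be accepted),
* near-miss decoys violating it, e.g. dH = 2 with dcharge = 1 (must be
  rejected),
* one formula conflict (non-H composition differs; must be rejected).

Template reactions are written against the template's protonation states;
any hydrogen/charge residual caused by the planted shifts is compensated
with free-proton terms, exactly like real paired biochemistries, so both
models stay perfectly balanced.  The generator also emits the ground-truth
answer key (which pair is real, with which proton delta, and which source
reaction maps onto which template reaction in which direction).
"""

from __future__ import annotations

import random
from fractions import Fraction

import pandas as pd

from ..core import (
    ElementFormula,
    MetabolicModel,
    Metabolite,
    Reaction,
    assert_balanced,
)
from . import FixtureBundle
from .chem import INF, COMPARTMENT_NAMES

SOURCE_NS = "biocyc"
TEMPLATE_NS = "bigg"
BRIDGE_NS = "metanetx"
THIRD_NS = "kegg"


def _random_formula(rng: random.Random) -> tuple[dict[str, int], int]:
    counts = {
        "C": rng.randint(1, 8),
        "H": rng.randint(2, 14),
        "O": rng.randint(1, 8),
    }
    if rng.random() < 0.5:
        counts["N"] = rng.randint(1, 3)
    if rng.random() < 0.3:
        counts["P"] = rng.randint(1, 2)
    charge = rng.randint(-2, 1)
    return counts, charge


def make_mapping_fixture(
    n_metabolites: int = 12,
    n_protonation_mismatches: int = 3,
    seed: int = 1,
    n_formula_conflicts: int = 1,
    n_decoys: int = 2,
    n_reactions: int = 8,
) -> FixtureBundle:
    """Build the mapping fixture; ``n_metabolites`` true species pairs, of
    which ``n_protonation_mismatches`` differ by a pure protonation shift and
    ``n_formula_conflicts`` have corrupted template formulas (planted
    mapping errors that verification must catch)."""
    if n_protonation_mismatches + n_formula_conflicts > n_metabolites:
        raise ValueError("more planted anomalies than metabolites")
    rng = random.Random(seed)

    n_generators = max(2, n_metabolites // 2)
    formulas: list[dict[str, int]] = []
    charges: list[int] = []
    for _ in range(n_generators):
        counts, charge = _random_formula(rng)
        formulas.append(counts)
        charges.append(charge)
    # composite species: elemental sum of two generators, so that a reaction
    # "a + b -> composite" is balanced by construction
    composites: list[tuple[int, int]] = []
    for _ in range(n_metabolites - n_generators):
        a, b = rng.randrange(n_generators), rng.randrange(n_generators)
        counts = dict(formulas[a])
        for el, n in formulas[b].items():
            counts[el] = counts.get(el, 0) + n
        formulas.append(counts)
        charges.append(charges[a] + charges[b])
        composites.append((a, b))

    shifted = set(rng.sample(range(n_metabolites), n_protonation_mismatches))
    conflicted = set()
    pool = [i for i in range(n_metabolites) if i not in shifted]
    conflicted = set(rng.sample(pool, n_formula_conflicts))

    source = MetabolicModel(id="mapping_source",
                           compartments={"c": COMPARTMENT_NAMES["c"]})
    template = MetabolicModel(id="mapping_template",
                              compartments={"c": COMPARTMENT_NAMES["c"]})

    def src_id(i: int) -> str:
        return f"CPD-{i:03d}"

    def tmpl_id(i: int) -> str:
        return f"m{i:03d}"

    # the proton pair (always present; bridged via the bridge namespace)
    source.add_metabolite(Metabolite("PROTON_c", name="H+",
                                     formula=ElementFormula({"H": 1}), charge=1,
                                     compartment="c"))
    template.add_metabolite(Metabolite("h_c", name="H+",
                                       formula=ElementFormula({"H": 1}), charge=1,
                                       compartment="c"))

    truth_rows = []
    deltas: dict[int, int] = {}
    for i in range(n_metabolites):
        sf, sq = dict(formulas[i]), charges[i]
        tf, tq = dict(sf), sq
        status, delta = "verified", 0
        if i in shifted:
            delta = rng.choice([-1, 1, 2])
            if sf.get("H", 0) + delta < 1:
                delta = 1
            tf["H"] = tf.get("H", 0) + delta
            tq += delta
            status = "verified"
        elif i in conflicted:
            tf["O"] = tf.get("O", 0) + 1  # non-H corruption
            status, delta = "rejected_formula", 0
        deltas[i] = delta if status == "verified" else 0
        source.add_metabolite(
            Metabolite(f"{src_id(i)}_c", name=src_id(i),
                       formula=ElementFormula(sf), charge=sq, compartment="c"))
        template.add_metabolite(
            Metabolite(f"{tmpl_id(i)}_c", name=tmpl_id(i),
                       formula=ElementFormula(tf), charge=tq, compartment="c"))
        truth_rows.append({
            "source_metabolite_id": src_id(i),
            "template_metabolite_id": tmpl_id(i),
            "status": status,
            "proton_delta": delta if status == "verified" else None,
        })

    # decoys: extra template species linked to a source species but with a
    # hydrogen shift that the charge does not follow (dH=2, dq=1)
    decoy_targets = rng.sample(range(n_metabolites), min(n_decoys, n_metabolites))
    decoy_rows = []
    for i in decoy_targets:
        did = f"{tmpl_id(i)}_decoy"
        tf = dict(formulas[i])
        tf["H"] = tf.get("H", 0) + 2
        template.add_metabolite(
            Metabolite(f"{did}_c", name=did, formula=ElementFormula(tf),
                       charge=charges[i] + 1, compartment="c"))
        decoy_rows.append({
            "source_metabolite_id": src_id(i),
            "template_metabolite_id": did,
            "status": "rejected_charge",
            "proton_delta": None,
        })

    # --- cross-reference tables (provenance rotates by index) ---------------
    direct, bridge, src_ann, tmpl_ann = [], [], {}, {}
    for i in range(n_metabolites):
        kind = i % 3
        if kind == 0:
            direct.append({"source_ns": SOURCE_NS, "source_id": src_id(i),
                           "target_ns": TEMPLATE_NS, "target_id": tmpl_id(i)})
        elif kind == 1:
            mnx = f"MNXM{i:04d}"
            bridge.append({"bridge_ns": BRIDGE_NS, "bridge_id": mnx,
                           "member_ns": SOURCE_NS, "member_id": src_id(i)})
            bridge.append({"bridge_ns": BRIDGE_NS, "bridge_id": mnx,
                           "member_ns": TEMPLATE_NS, "member_id": tmpl_id(i)})
        else:
            kegg = f"C{10000 + i}"
            src_ann.setdefault(src_id(i), {})[THIRD_NS] = [kegg]
            tmpl_ann.setdefault(tmpl_id(i), {})[THIRD_NS] = [kegg]
            source.metabolites[f"{src_id(i)}_c"].xrefs[THIRD_NS] = [kegg]
            template.metabolites[f"{tmpl_id(i)}_c"].xrefs[THIRD_NS] = [kegg]
    for i in decoy_targets:
        direct.append({"source_ns": SOURCE_NS, "source_id": src_id(i),
                       "target_ns": TEMPLATE_NS, "target_id": f"{tmpl_id(i)}_decoy"})
    bridge.append({"bridge_ns": BRIDGE_NS, "bridge_id": "MNXM1",
                   "member_ns": SOURCE_NS, "member_id": "PROTON"})
    bridge.append({"bridge_ns": BRIDGE_NS, "bridge_id": "MNXM1",
                   "member_ns": TEMPLATE_NS, "member_id": "h"})

    # --- reactions over cleanly matched composite species -------------------
    usable = [i for i in range(n_metabolites) if i not in conflicted]
    rxn_truth = []
    n_rxn = 0
    for j, (a, b) in enumerate(composites):
        i_comp = n_generators + j
        if i_comp in conflicted or a in conflicted or b in conflicted:
            continue
        if n_rxn >= n_reactions:
            break
        n_rxn += 1
        rid_s, rid_t = f"RXN-{j:03d}", f"R{j:03d}"
        src_stoich: dict[str, Fraction] = {}
        for idx, coeff in ((a, -1), (b, -1), (i_comp, 1)):
            key = f"{src_id(idx)}_c"
            src_stoich[key] = src_stoich.get(key, Fraction(0)) + coeff
        source.add_reaction(Reaction(rid_s, stoichiometry=src_stoich,
                                     lower_bound=-INF, upper_bound=INF))
        # template side: same chemistry in the template's protonation states;
        # the residual hydrogen shift is compensated with free protons
        residual = deltas[i_comp] - deltas[a] - deltas[b]
        t_stoich: dict[str, Fraction] = {}
        for idx, coeff in ((a, -1), (b, -1), (i_comp, 1)):
            key = f"{tmpl_id(idx)}_c"
            t_stoich[key] = t_stoich.get(key, Fraction(0)) + coeff
        reversed_writing = rng.random() < 0.4
        if residual:
            t_stoich["h_c"] = Fraction(-residual)
        if reversed_writing:
            t_stoich = {m: -c for m, c in t_stoich.items()}
        template.add_reaction(Reaction(rid_t, stoichiometry=t_stoich,
                                       lower_bound=-INF, upper_bound=INF))
        rxn_truth.append({"source_reaction_id": rid_s,
                          "template_reaction_id": rid_t,
                          "direction": "reversed" if reversed_writing else "same"})

    # one source reaction with an unmappable (acyl-carrier-style) species
    acp_formula = {"C": 120, "H": 190, "N": 30, "O": 36, "S": 2}
    source.add_metabolite(Metabolite("ACP-CPLX_c", name="acyl carrier complex",
                                     formula=ElementFormula(acp_formula),
                                     charge=0, compartment="c"))
    carrier_sub = usable[0]
    loaded = dict(acp_formula)
    for el, n in formulas[carrier_sub].items():
        loaded[el] = loaded.get(el, 0) + n
    source.add_metabolite(Metabolite("ACP-CPLX-LOADED_c", name="loaded carrier",
                                     formula=ElementFormula(loaded),
                                     charge=charges[carrier_sub],
                                     compartment="c"))
    source.add_reaction(Reaction(
        "ACP-LOAD-RXN",
        stoichiometry={f"{src_id(carrier_sub)}_c": Fraction(-1),
                       "ACP-CPLX_c": Fraction(-1),
                       "ACP-CPLX-LOADED_c": Fraction(1)},
        lower_bound=0, upper_bound=INF))
    rxn_truth.append({"source_reaction_id": "ACP-LOAD-RXN",
                      "template_reaction_id": None, "direction": None})

    assert_balanced(source)
    assert_balanced(template)

    bundle = FixtureBundle(name="mapping", seed=seed,
                           models={"mapping_source": source,
                                   "mapping_template": template})
    bundle.tables["direct_links"] = pd.DataFrame(
        direct, columns=["source_ns", "source_id", "target_ns", "target_id"])
    bundle.tables["bridge_metanetx"] = pd.DataFrame(
        bridge, columns=["bridge_ns", "bridge_id", "member_ns", "member_id"])
    bundle.specs["annotations"] = {SOURCE_NS: src_ann, TEMPLATE_NS: tmpl_ann}
    truth_rows.append({"source_metabolite_id": "PROTON",
                       "template_metabolite_id": "h",
                       "status": "verified", "proton_delta": 0})
    bundle.ground_truth = {
        "source_ns": SOURCE_NS,
        "template_ns": TEMPLATE_NS,
        "metabolite_matches": truth_rows,
        "decoys": decoy_rows,
        "reaction_matches": rxn_truth,
        "n_verified": n_metabolites - n_formula_conflicts + 1,
        "n_rejected_formula": n_formula_conflicts,
    }
    return bundle


def fixture_annotations(bundle: FixtureBundle) -> dict:
    """The third-party annotation argument for build_xref_graph."""
    return bundle.specs["annotations"]
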