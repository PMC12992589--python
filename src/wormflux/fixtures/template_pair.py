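"""End-to-end compartmentalization fixture: a flat source model in a
BioCyc-style namespace plus a compartmentalized template in a BiGG-style
namespace, with cross-reference tables, a manual-assignment table and the
ground-truth compartment plan and transporter-graft set.

The scenario mirrors the real workflow: the flat model keeps everything in
the cytosol except reactions it explicitly designates as mitochondrial; the
template localizes malate dehydrogenase and malic enzyme in the
mitochondrion (so those two source reactions must be relocated), carries
c<->m transporters for pyruvate, phosphate, malate and succinate (all
graftable) and for citrate (absent from the source, hence skipped), and one
source reaction uses an explicit acyl-carrier species that the template
models without carriers, so it cannot be mapped and stays unresolved.
Succinate is stored in different protonation states on the two sides
(monoanion vs dianion), exercising protonation-tolerant matching.
"""

from __future__ import annotations

import random
from fractions import Fraction

import pandas as pd

from ..core import ElementFormula, assert_balanced
from . import FixtureBundle
from .chem import FORMULAS, INF, ModelBuilder

SOURCE_NS = "biocyc"
TEMPLATE_NS = "bigg"

#: source (BioCyc-style) name -> template (BiGG-style) name
NAME_MAP = {
    "GLC": "glc__D",
    "ATP": "atp",
    "ADP": "adp",
    "Pi": "pi",
    "PROTON": "h",
    "WATER": "h2o",
    "NAD": "nad",
    "NADH": "nadh",
    "PYRUVATE": "pyr",
    "FRU16BP": "fdp",
    "F6P": "f6p",
    "G3P": "pg3",
    "OXALACETIC-ACID": "oaa",
    "MAL": "mal__L",
    "CO2": "co2",
    "OXYGEN": "o2",
    "SUC": "succ",
    "L-LACTATE": "lac__L",
    "GTP": "gtp",
    "GDP": "gdp",
}

#: provenance route per source name: how the xref tables connect the pair
_ROUTE = {
    "PROTON": "bridge",    # the MNXM1-style bridge entry
    "PYRUVATE": "kegg",    # shared third-party identifier
    "MAL": "kegg",
    "SUC": "bridge",
}


class _PairBuilder(ModelBuilder):
    """Builder whose species table is the shared chemistry under either the
    source or the template naming."""

    def __init__(self, model_id, compartments, naming: dict[str, str]):
        super().__init__(model_id, compartments)
        for local, canonical in naming.items():
            text, charge = FORMULAS[canonical]
            self.define_species(local, ElementFormula(text), charge)


def make_template_pair(seed: int = 0) -> FixtureBundle:
    rng = random.Random(seed)

    # --- source: flat, BioCyc-style ----------------------------------------
    src_names = {name: name for name in NAME_MAP}
    sb = _PairBuilder("flat_source", ["c", "m"],
                      {n: c for n, c in NAME_MAP.items()})
    # succinate monoanion on the source side (protonation mismatch, dH=dq=+1
    # from the template's dianion)
    sb.define_species("SUC", ElementFormula("C4H5O4"), -1)

    sb.rxn("GLYC-LUMP1", {("GLC", "c"): -1, ("ATP", "c"): -2,
                          ("FRU16BP", "c"): 1, ("ADP", "c"): 2,
                          ("PROTON", "c"): 2})
    sb.rxn("GLYC-LUMP2", {("FRU16BP", "c"): -1, ("NAD", "c"): -2,
                          ("Pi", "c"): -2, ("ADP", "c"): -2,
                          ("G3P", "c"): 2, ("NADH", "c"): 2,
                          ("ATP", "c"): 2, ("PROTON", "c"): 2})
    sb.rxn("PYK-LUMP", {("G3P", "c"): -1, ("ADP", "c"): -1, ("PROTON", "c"): -1,
                        ("PYRUVATE", "c"): 1, ("ATP", "c"): 1, ("WATER", "c"): 1})
    sb.rxn("6PFRUCTPHOS-RXN", {("F6P", "c"): -1, ("ATP", "c"): -1,
                               ("FRU16BP", "c"): 1, ("ADP", "c"): 1,
                               ("PROTON", "c"): 1},
           ec=["2.7.1.11"])
    sb.rxn("MDH-RXN", {("MAL", "c"): -1, ("NAD", "c"): -1,
                       ("OXALACETIC-ACID", "c"): 1, ("NADH", "c"): 1,
                       ("PROTON", "c"): 1},
           lb=-INF, ec=["1.1.1.37"])
    sb.rxn("MALIC-RXN", {("MAL", "c"): -1, ("NAD", "c"): -1,
                         ("PYRUVATE", "c"): 1, ("CO2", "c"): 1,
                         ("NADH", "c"): 1},
           ec=["1.1.1.38"])
    sb.rxn("LDH-RXN", {("PYRUVATE", "c"): -1, ("NADH", "c"): -1,
                       ("PROTON", "c"): -1,
                       ("L-LACTATE", "c"): 1, ("NAD", "c"): 1},
           lb=-INF, ec=["1.1.1.27"])
    # explicitly designated mitochondrial: stays put regardless of mapping
    sb.rxn("RESP-RXN", {("NADH", "m"): -1, ("OXYGEN", "m"): Fraction(-1, 2),
                        ("PROTON", "m"): -1,
                        ("NAD", "m"): 1, ("WATER", "m"): 1},
           flags={"mitochondrial_designated"})
    # no template counterpart; assigned manually
    sb.rxn("NDK-RXN", {("GTP", "c"): -1, ("ADP", "c"): -1,
                       ("GDP", "c"): 1, ("ATP", "c"): 1},
           lb=-INF, ec=["2.7.4.6"])
    # acyl-carrier chemistry made explicit only on the source side
    acp = ElementFormula({"C": 120, "H": 190, "N": 30, "O": 36, "S": 2})
    sb.define_species("ACP-CPLX", acp, 0)
    mal_f, mal_q = FORMULAS["mal__L"]
    loaded_counts = {el: n for el, n in acp.items()}
    for el, n in ElementFormula(mal_f).items():
        loaded_counts[el] = loaded_counts.get(el, 0) + n
    loaded_counts["H"] -= 2
    loaded_counts["O"] -= 1
    sb.define_species("ACP-CPLX-MAL", ElementFormula(loaded_counts), mal_q)
    sb.rxn("ACP-LOAD-RXN", {("MAL", "c"): -1, ("ACP-CPLX", "c"): -1,
                            ("ACP-CPLX-MAL", "c"): 1, ("WATER", "c"): 1})
    # anchor succinate in the source (no template counterpart for the
    # dehydrogenase lump, so the reaction itself stays unresolved)
    sb.define_species("FUM", ElementFormula(FORMULAS["fum"][0]),
                      FORMULAS["fum"][1])
    sb.rxn("SUCCDEHYDROG-RXN", {("SUC", "c"): -1, ("NAD", "c"): -1,
                                ("FUM", "c"): 1, ("NADH", "c"): 1,
                                ("PROTON", "c"): 2},
           ec=["1.3.5.1"])
    source = sb.model

    # --- template: compartmentalized, BiGG-style ----------------------------
    tb = _PairBuilder("template", ["c", "m", "e"], {})
    tb.rxn("GLY1", {("glc__D", "c"): -1, ("atp", "c"): -2,
                    ("fdp", "c"): 1, ("adp", "c"): 2, ("h", "c"): 2})
    tb.rxn("GLY2", {("fdp", "c"): -1, ("nad", "c"): -2, ("pi", "c"): -2,
                    ("adp", "c"): -2, ("pg3", "c"): 2, ("nadh", "c"): 2,
                    ("atp", "c"): 2, ("h", "c"): 2})
    # written in the opposite direction to the source's PYK-LUMP
    tb.rxn("PYK", {("pyr", "c"): -1, ("atp", "c"): -1, ("h2o", "c"): -1,
                   ("pg3", "c"): 1, ("adp", "c"): 1, ("h", "c"): 1},
           lb=-INF, ec=["2.7.1.40"])
    tb.rxn("PFK", {("f6p", "c"): -1, ("atp", "c"): -1,
                   ("fdp", "c"): 1, ("adp", "c"): 1, ("h", "c"): 1},
           ec=["2.7.1.11"])
    tb.rxn("MDHm", {("mal__L", "m"): -1, ("nad", "m"): -1,
                    ("oaa", "m"): 1, ("nadh", "m"): 1, ("h", "m"): 1},
           lb=-INF, ec=["1.1.1.37"])
    tb.rxn("ME1m", {("mal__L", "m"): -1, ("nad", "m"): -1,
                    ("pyr", "m"): 1, ("co2", "m"): 1, ("nadh", "m"): 1},
           ec=["1.1.1.38"])
    tb.rxn("LDH_L", {("pyr", "c"): -1, ("nadh", "c"): -1, ("h", "c"): -1,
                     ("lac__L", "c"): 1, ("nad", "c"): 1},
           lb=-INF, ec=["1.1.1.27"])
    tb.rxn("RESPm", {("nadh", "m"): -1, ("o2", "m"): Fraction(-1, 2),
                     ("h", "m"): -1, ("nad", "m"): 1, ("h2o", "m"): 1})
    # c<->m transporters: four graftable, one (citrate) not present in source
    tb.rxn("PYRt2m", {("pyr", "c"): -1, ("h", "c"): -1,
                      ("pyr", "m"): 1, ("h", "m"): 1},
           lb=-INF, flags={"transporter"})
    tb.rxn("PIt2m", {("pi", "c"): -1, ("h", "c"): -1,
                     ("pi", "m"): 1, ("h", "m"): 1},
           lb=-INF, flags={"transporter"})
    tb.rxn("MALt2m", {("mal__L", "c"): -1, ("h", "c"): -2,
                      ("mal__L", "m"): 1, ("h", "m"): 2},
           lb=-INF, flags={"transporter"})
    tb.rxn("SUCCt2m", {("succ", "c"): -1, ("h", "c"): -2,
                       ("succ", "m"): 1, ("h", "m"): 2},
           lb=-INF, flags={"transporter"})
    tb.define_species("cit", ElementFormula("C6H5O7"), -3)
    tb.rxn("CITtam", {("cit", "c"): -1, ("cit", "m"): 1},
           lb=-INF, flags={"transporter"})
    template = tb.model
    # a cytosolic succinate instance so the species exists for matching
    template.instantiate(template.metabolites["succ_c"], "c")

    assert_balanced(source)
    assert_balanced(template)

    # --- cross-reference tables ---------------------------------------------
    direct, bridge, src_ann, tmpl_ann = [], [], {}, {}
    for i, (src, tmpl) in enumerate(sorted(NAME_MAP.items())):
        route = _ROUTE.get(src, "direct")
        if route == "direct":
            direct.append({"source_ns": SOURCE_NS, "source_id": src,
                           "target_ns": TEMPLATE_NS, "target_id": tmpl})
        elif route == "bridge":
            mnx = f"MNXM{i + 1:04d}"
            bridge.append({"bridge_ns": "metanetx", "bridge_id": mnx,
                           "member_ns": SOURCE_NS, "member_id": src})
            bridge.append({"bridge_ns": "metanetx", "bridge_id": mnx,
                           "member_ns": TEMPLATE_NS, "member_id": tmpl})
        else:
            kegg = f"C{20000 + i}"
            src_ann.setdefault(src, {})["kegg"] = [kegg]
            tmpl_ann.setdefault(tmpl, {})["kegg"] = [kegg]
            # annotations live on the species, as in real SBML exports
            source.metabolites[f"{src}_c"].xrefs["kegg"] = [kegg]
            for met in template.metabolites.values():
                if met.base_id() == tmpl:
                    met.xrefs["kegg"] = [kegg]
    rng.shuffle(direct)  # row order must not matter

    manual = pd.DataFrame(
        [{"reaction_id": "NDK-RXN", "compartment_id": "m"}],
        columns=["reaction_id", "compartment_id"],
    )

    bundle = FixtureBundle(name="template_pair", seed=seed,
                           models={"flat_source": source, "template": template})
    bundle.tables["direct_links"] = pd.DataFrame(
        direct, columns=["source_ns", "source_id", "target_ns", "target_id"])
    bundle.tables["bridge_metanetx"] = pd.DataFrame(
        bridge, columns=["bridge_ns", "bridge_id", "member_ns", "member_id"])
    bundle.tables["manual_assignments"] = manual
    bundle.specs["annotations"] = {SOURCE_NS: src_ann, TEMPLATE_NS: tmpl_ann}
    bundle.ground_truth = {
        "source_ns": SOURCE_NS,
        "template_ns": TEMPLATE_NS,
        "metabolite_matches": {
            s: t for s, t in NAME_MAP.items() if s not in ("GTP", "GDP")
        },
        "unmatched_source": ["ACP-CPLX", "ACP-CPLX-MAL", "FUM", "GDP", "GTP"],
        "succinate_proton_delta": -1,  # template dianion has one H fewer
        "reaction_matches": {
            "GLYC-LUMP1": ["GLY1", "same"],
            "GLYC-LUMP2": ["GLY2", "same"],
            "PYK-LUMP": ["PYK", "reversed"],
            "6PFRUCTPHOS-RXN": ["PFK", "same"],
            "MDH-RXN": ["MDHm", "same"],
            "MALIC-RXN": ["ME1m", "same"],
            "LDH-RXN": ["LDH_L", "same"],
            "RESP-RXN": ["RESPm", "same"],
            "NDK-RXN": None,
            "ACP-LOAD-RXN": None,
            "SUCCDEHYDROG-RXN": None,
        },
        "plan": {
            "GLYC-LUMP1": ["c", "template_transfer"],
            "GLYC-LUMP2": ["c", "template_transfer"],
            "PYK-LUMP": ["c", "template_transfer"],
            "6PFRUCTPHOS-RXN": ["c", "template_transfer"],
            "MDH-RXN": ["m", "template_transfer"],
            "MALIC-RXN": ["m", "template_transfer"],
            "LDH-RXN": ["c", "template_transfer"],
            "RESP-RXN": ["m", "source_designation"],
            "NDK-RXN": ["m", "manual"],
        },
        "unresolved": ["ACP-LOAD-RXN", "SUCCDEHYDROG-RXN"],
        "grafted_transporters": ["MALt2m", "PIt2m", "PYRt2m", "SUCCt2m"],
        "skipped_transporters": ["CITtam"],
    }
    return bundle
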