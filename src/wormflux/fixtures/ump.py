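"""UMP-biosynthesis fixture: a de-novo pyrimidine pathway broken by
compartment separation.

The pathway (carbamoyl-P -> carbamoyl-aspartate -> dihydroorotate -> orotate
-> OMP -> UMP) is cytosolic except that dihydroorotate dehydrogenase is an
inner-mitochondrial-membrane flavoenzyme feeding electrons into the quinone
pool.  The raw fixture writes that enzyme in the cytosol against a generic
quinone couple that nothing regenerates, so UMP production is infeasible.
The curation pair — relocating the enzyme against the mitochondrial
quinone/quinol couple with its substrate side in the intermembrane space,
plus technical outer-membrane shuttles for dihydroorotate and orotate —
makes the pathway operational.  An optional uracil-salvage route is feasible
even before the fix.
"""

from __future__ import annotations

from fractions import Fraction

from ..core import Reaction, assert_balanced
from . import FixtureBundle
from .chem import INF, ModelBuilder

DHODH_ID = "DHODH"
UMP_DEMAND_ID = "DM_ump_c"


def make_ump_fixture(salvage: bool = False, seed: int = 0) -> FixtureBundle:
    """Build the UMP fixture.

    With ``salvage=True`` an alternative uracil route to UMP is included,
    which works regardless of the dehydrogenase localization.
    """
    b = ModelBuilder("ump_pathway", ["c", "m", "i", "e"])
    model = b.model

    uptakes = {
        "gln__L": 10.0,
        "asp__L": 10.0,
        "hco3": 10.0,
        "prpp": 10.0,
        "o2": 1000.0,
        "h2o": 1000.0,
        "h": 1000.0,
    }
    if salvage:
        uptakes["ura"] = 10.0
    for base, rate in uptakes.items():
        b.exchange(base, rate)
        b.rxn(f"{base.upper().replace('__', '_')}t",
              {(base, "e"): -1, (base, "c"): 1}, lb=-INF, flags={"transporter"})
    for base in ["co2", "glu__L", "pi"]:
        b.exchange(base)
        b.rxn(f"{base.upper().replace('__', '_')}t",
              {(base, "e"): -1, (base, "c"): 1}, lb=-INF, flags={"transporter"})
        b.allow_secretion(base)
    for base in ["h", "h2o"]:
        b.allow_secretion(base)

    # carbamoyl-phosphate synthetase (glutamine-hydrolyzing) lump
    b.rxn("CPS", {("gln__L", "c"): -1, ("hco3", "c"): -1, ("atp", "c"): -2,
                  ("h2o", "c"): -1,
                  ("cbp", "c"): 1, ("glu__L", "c"): 1, ("adp", "c"): 2,
                  ("pi", "c"): 1, ("h", "c"): 2},
          ec=["6.3.5.5"])
    # ATP supplied by a maintenance-style regeneration pseudo-pair so the
    # fixture stays focused on the pyrimidine chemistry
    b.rxn("ATPREGEN", {("adp", "c"): -1, ("pi", "c"): -1, ("h", "c"): -1,
                       ("atp", "c"): 1, ("h2o", "c"): 1})
    b.rxn("ATCASE", {("cbp", "c"): -1, ("asp__L", "c"): -1,
                     ("cbasp", "c"): 1, ("pi", "c"): 1, ("h", "c"): 1},
          ec=["2.1.3.2"])
    b.rxn("DHOASE", {("cbasp", "c"): -1, ("h", "c"): -1,
                     ("dhor__S", "c"): 1, ("h2o", "c"): 1},
          lb=-INF, ec=["3.5.2.3"])
    # the broken enzyme: cytosolic, against a generic quinone couple with no
    # regeneration — a structural dead end
    b.rxn(DHODH_ID, {("dhor__S", "c"): -1, ("q", "c"): -1,
                     ("orot", "c"): 1, ("qh2", "c"): 1},
          ec=["1.3.5.2"])
    b.rxn("ORPT", {("orot", "c"): -1, ("prpp", "c"): -1,
                   ("omp", "c"): 1, ("ppi", "c"): 1},
          ec=["2.4.2.10"])
    b.rxn("OMPDC", {("omp", "c"): -1, ("h", "c"): -1,
                    ("ump", "c"): 1, ("co2", "c"): 1},
          ec=["4.1.1.23"])
    b.rxn("PPASE", {("ppi", "c"): -1, ("h2o", "c"): -1,
                    ("pi", "c"): 2, ("h", "c"): 1},
          ec=["3.6.1.1"])
    if salvage:
        b.rxn("UPPRT", {("ura", "c"): -1, ("prpp", "c"): -1,
                        ("ump", "c"): 1, ("ppi", "c"): 1},
              ec=["2.4.2.9"])

    # the mitochondrial quinone pool, regenerated by respiration
    b.rxn("QOX", {("qh2", "m"): -1, ("o2", "m"): Fraction(-1, 2),
                  ("q", "m"): 1, ("h2o", "m"): 1})
    b.rxn("O2tm", {("o2", "c"): -1, ("o2", "m"): 1}, lb=-INF,
          flags={"transporter"})
    b.rxn("H2Otm", {("h2o", "c"): -1, ("h2o", "m"): 1}, lb=-INF,
          flags={"transporter"})

    # UMP demand: the feasibility probe for the whole pathway
    model.add_reaction(Reaction(
        id=UMP_DEMAND_ID, name="UMP demand",
        stoichiometry={b.met("ump", "c"): Fraction(-1)},
        lower_bound=0.0, upper_bound=INF, flags={"demand"},
    ))

    assert_balanced(model)
    model.validate()

    bundle = FixtureBundle(name="ump_pathway", seed=seed,
                           models={"ump_pathway": model})
    bundle.ground_truth = {
        "demand": UMP_DEMAND_ID,
        "dhodh": DHODH_ID,
        "quinone_couple": ["q_m", "qh2_m"],
        "shuttle_metabolites": ["dhor__S_c", "orot_c"],
        "feasible_before_fix": bool(salvage),
        "feasible_after_fix": True,
        "salvage": salvage,
    }
    return bundle


def apply_ump_curation(model, log: list | None = None):
    """Convenience: the two-step repair on the fixture — relocate the
    dehydrogenase to the inner membrane and add both outer-membrane
    shuttles."""
    from ..curation import add_intermembrane_shuttle, fix_quinone_coupled_enzyme

    # the mitochondrial quinone couple may not exist yet in the raw fixture
    for base in ("q", "qh2"):
        if model.find_metabolite(base, "m") is None:
            model.instantiate(model.find_metabolite(base, "c"), "m")
    fix_quinone_coupled_enzyme(model, DHODH_ID, "q_m", "qh2_m", log=log)
    add_intermembrane_shuttle(model, "dhor__S_c", log=log)
    add_intermembrane_shuttle(model, "orot_c", log=log)
    return model
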