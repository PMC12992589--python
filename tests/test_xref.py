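"""Protonation-tolerant matching: the compatibility rule, the xref graph,
and full metabolite/reaction matching against generator answer keys."""

import random

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormflux import xref
from wormflux.core import ElementFormula
from wormflux.fixtures import make_mapping_fixture
from wormflux.fixtures.mapping import fixture_annotations


class TestProtonationCompatible:
    def test_lactate_lactic_acid_shift_accepted(self):
        ok, delta = xref.protonation_compatible(
            ElementFormula("C3H5O3"), -1, ElementFormula("C3H6O3"), 0)
        assert ok and delta == 1

    def test_identity_accepted_with_zero_delta(self):
        ok, delta = xref.protonation_compatible(
            ElementFormula("C6H12O6"), 0, ElementFormula("C6H12O6"), 0)
        assert ok and delta == 0

    def test_hydrogen_shift_without_matching_charge_rejected(self):
        # dH = 2 but dq = 1: not a protonation state change
        ok, delta = xref.protonation_compatible(
            ElementFormula("C4H4O5"), -2, ElementFormula("C4H6O5"), -1)
        assert not ok

    def test_rule_equals_brute_force_over_all_shift_pairs(self):
        base = ElementFormula("C4H6O4")
        for dh in range(-3, 4):
            for dq in range(-3, 4):
                counts = dict(base.items())
                counts["H"] += dh
                shifted = ElementFormula(counts)
                ok, delta = xref.protonation_compatible(base, -1, shifted, -1 + dq)
                assert ok == (dh == dq)
                if ok:
                    assert delta == dh

    def test_non_h_difference_always_rejected(self):
        ok, _ = xref.protonation_compatible(
            ElementFormula("C3H5O3"), -1, ElementFormula("C3H5O4"), -1)
        assert not ok

    def test_unknown_formula_never_compatible(self):
        assert xref.protonation_compatible(None, 0, ElementFormula("H2O"), 0) == (
            False, None)

    @given(
        c=st.integers(1, 9), h=st.integers(1, 20), o=st.integers(0, 9),
        q=st.integers(-3, 3), d=st.integers(-2, 2),
    )
    def test_symmetry_up_to_delta_sign(self, c, h, o, q, d):
        a = ElementFormula({"C": c, "H": h, "O": o})
        if h + d < 0:
            return
        b = ElementFormula({"C": c, "H": h + d, "O": o})
        ok_ab, d_ab = xref.protonation_compatible(a, q, b, q + d)
        ok_ba, d_ba = xref.protonation_compatible(b, q + d, a, q)
        assert ok_ab and ok_ba
        assert d_ab == -d_ba == d

    def test_compatible_with_itself(self):
        f = ElementFormula("C10H12N5O13P3")
        assert xref.protonation_compatible(f, -4, f, -4) == (True, 0)


class TestGraphBuilding:
    def test_direct_link_single_edge(self):
        links = pd.DataFrame([{"source_ns": "BC", "source_id": "GLC",
                               "target_ns": "BG", "target_id": "glc__D"}])
        g = xref.build_xref_graph("BC", "BG", direct_links=links)
        assert g.candidate_template_ids("GLC") == {"glc__D": {"direct_link"}}

    def test_shared_third_party_edge_derived_from_annotations(self):
        ann = {"BC": {"PYRUVATE": {"kegg": ["C00022"]}},
               "BG": {"pyr": {"kegg": ["C00022"]}}}
        g = xref.build_xref_graph("BC", "BG", third_party_annotations=ann)
        assert g.candidate_template_ids("PYRUVATE") == {
            "pyr": {"shared_third_party"}}

    def test_bridge_entry_collapsed_to_member_edge(self):
        bridge = pd.DataFrame([
            {"bridge_ns": "MNX", "bridge_id": "MNXM1",
             "member_ns": "BC", "member_id": "PROTON"},
            {"bridge_ns": "MNX", "bridge_id": "MNXM1",
             "member_ns": "BG", "member_id": "h"},
        ])
        g = xref.build_xref_graph("BC", "BG", bridge_tables=[bridge])
        assert g.candidate_template_ids("PROTON") == {"h": {"bridge_table"}}

    def test_contradictory_rows_both_kept(self):
        links = pd.DataFrame([
            {"source_ns": "BC", "source_id": "A", "target_ns": "BG",
             "target_id": "x"},
            {"source_ns": "BC", "source_id": "A", "target_ns": "BG",
             "target_id": "y"},
        ])
        g = xref.build_xref_graph("BC", "BG", direct_links=links)
        assert set(g.candidate_template_ids("A")) == {"x", "y"}


def _graph_for(bundle):
    return xref.build_xref_graph(
        bundle.ground_truth["source_ns"],
        bundle.ground_truth["template_ns"],
        direct_links=bundle.tables["direct_links"],
        bridge_tables=[bundle.tables["bridge_metanetx"]],
        third_party_annotations=fixture_annotations(bundle),
    )


def _brute_force_match(source, template, graph):
    """Independent oracle: all-pairs element-wise comparison restricted to
    graph-connected pairs, with plain dict arithmetic."""
    chosen = {}
    for s_met in source.metabolites.values():
        s_base = s_met.base_id()
        cands = graph.candidate_template_ids(s_base)
        best = None
        for t_base in cands:
            t_met = next(
                (m for m in sorted(template.metabolites.values(),
                                   key=lambda m: m.id)
                 if m.base_id() == t_base), None)
            if t_met is None or s_met.formula is None or t_met.formula is None:
                continue
            sf = dict(s_met.formula.items())
            tf = dict(t_met.formula.items())
            sf_nh = {k: v for k, v in sf.items() if k != "H"}
            tf_nh = {k: v for k, v in tf.items() if k != "H"}
            if sf_nh != tf_nh:
                continue
            if tf.get("H", 0) - sf.get("H", 0) != t_met.charge - s_met.charge:
                continue
            prio = max(xref.PROVENANCE_PRIORITY[p] for p in cands[t_base])
            key = (-prio, t_base)
            if best is None or key < best[0]:
                best = (key, t_base)
        if best:
            chosen[s_base] = best[1]
    return chosen


class TestMappingFixtureSuite:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_agree_with_answer_key_and_oracle(self, seed):
        bundle = make_mapping_fixture(12, 3, seed=seed)
        source = bundle.models["mapping_source"]
        template = bundle.models["mapping_template"]
        graph = _graph_for(bundle)
        matches = xref.match_metabolites(source, template, graph)
        selected = xref.selected_matches(matches)

        key = bundle.ground_truth
        for row in key["metabolite_matches"]:
            s = row["source_metabolite_id"]
            if row["status"] == "verified":
                assert selected[s] == row["template_metabolite_id"], (seed, s)
            else:
                assert s not in selected, (seed, s)
        assert len(selected) == key["n_verified"]
        # decoys violating dH = dq are reported as rejected, never selected
        by_pair = {(m.source_metabolite_id, m.template_metabolite_id): m
                   for m in matches}
        for row in key["decoys"]:
            m = by_pair[(row["source_metabolite_id"],
                         row["template_metabolite_id"])]
            assert m.status == xref.STATUS_REJECTED_CHARGE
            assert not m.selected
        assert selected == _brute_force_match(source, template, graph)

        rxn_matches = xref.match_reactions(source, template, matches)
        got = {m.source_reaction_id: (m.template_reaction_id, m.direction)
               for m in rxn_matches}
        for row in key["reaction_matches"]:
            assert got[row["source_reaction_id"]] == (
                row["template_reaction_id"], row["direction"]), (seed, row)

    def test_never_pairs_different_non_h_formulas(self):
        for seed in range(1, 11):
            bundle = make_mapping_fixture(12, 3, seed=seed)
            source = bundle.models["mapping_source"]
            template = bundle.models["mapping_template"]
            graph = _graph_for(bundle)
            for m in xref.match_metabolites(source, template, graph):
                if m.status != xref.STATUS_VERIFIED:
                    continue
                s = source.find_metabolite(m.source_metabolite_id, "c")
                t = template.find_metabolite(m.template_metabolite_id, "c")
                assert s.formula.without("H") == t.formula.without("H")


class TestProvenancePriority:
    def test_manual_beats_direct_and_both_reported(self, mapping_bundle):
        bundle = make_mapping_fixture(6, 0, seed=3, n_formula_conflicts=0)
        source = bundle.models["mapping_source"]
        template = bundle.models["mapping_template"]
        graph = _graph_for(bundle)
        # add a second verified candidate for CPD-000 via direct link, and a
        # manual assertion pointing at a different (also verified) species:
        # manual must win, both must be reported
        clone = template.metabolites["m000_c"]
        template = template.copy()
        template.add_metabolite(
            type(clone)(id="m999_c", name="clone", formula=clone.formula,
                        charge=clone.charge, compartment="c"))
        extra = pd.DataFrame([{"source_ns": "biocyc", "source_id": "CPD-000",
                               "target_ns": "bigg", "target_id": "m000"}])
        manual = pd.DataFrame([{"source_ns": "biocyc", "source_id": "CPD-000",
                                "target_ns": "bigg", "target_id": "m999"}])
        graph = xref.build_xref_graph(
            "biocyc", "bigg",
            direct_links=pd.concat(
                [bundle.tables["direct_links"], extra], ignore_index=True),
            bridge_tables=[bundle.tables["bridge_metanetx"]],
            third_party_annotations=fixture_annotations(bundle))
        matches = xref.match_metabolites(source, template, graph, manual)
        records = [m for m in matches if m.source_metabolite_id == "CPD-000"]
        assert {m.template_metabolite_id for m in records} >= {"m000", "m999"}
        (sel,) = [m for m in records if m.selected]
        assert sel.template_metabolite_id == "m999"
        assert sel.provenance == "manual"


class TestReactionMatchingInvariance:
    def test_reordering_and_direction_flip(self, mapping_bundle):
        bundle = mapping_bundle
        source = bundle.models["mapping_source"].copy()
        template = bundle.models["mapping_template"]
        graph = _graph_for(bundle)
        matches = xref.match_metabolites(source, template, graph)
        baseline = {m.source_reaction_id: (m.template_reaction_id, m.direction)
                    for m in xref.match_reactions(source, template, matches)}

        rng = random.Random(0)
        for rxn in source.reactions.values():
            items = list(rxn.stoichiometry.items())
            rng.shuffle(items)
            rxn.stoichiometry = dict(items)
        reordered = {m.source_reaction_id: (m.template_reaction_id, m.direction)
                     for m in xref.match_reactions(source, template, matches)}
        assert reordered == baseline

        # flipping the written direction of a reversible source reaction flips
        # only the reported direction
        flip_id = next(rid for rid, (tid, _) in baseline.items() if tid)
        rxn = source.reactions[flip_id]
        assert rxn.reversible
        rxn.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
        flipped = {m.source_reaction_id: (m.template_reaction_id, m.direction)
                   for m in xref.match_reactions(source, template, matches)}
        tid, direction = baseline[flip_id]
        assert flipped[flip_id] == (
            tid, "reversed" if direction == "same" else "same")
        assert {k: v for k, v in flipped.items() if k != flip_id} == {
            k: v for k, v in baseline.items() if k != flip_id}

    def test_exchange_demand_biomass_never_matched(self, core_model):
        matches = [
            xref.MetaboliteMatch("x", "x", "direct_link", 0, "verified", True)
        ]
        report = xref.match_reactions(core_model, core_model, matches)
        ids = {m.source_reaction_id for m in report}
        assert not any(r.startswith("EX_") for r in ids)
        assert "BIOMASS" not in ids
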