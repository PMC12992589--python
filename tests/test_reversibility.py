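"""Reversibility rules: decarboxylases, isomerases, energy-leak hydrolases
and proton-symport conversion, checked against the raw/refined fixture pair."""

import math
from fractions import Fraction

import pandas as pd
import pytest

from wormflux import qc
from wormflux.core import ModelError, check_balance
from wormflux.reversibility import (
    apply_rules,
    convert_to_proton_symport,
    fix_energy_leaks,
    make_decarboxylases_irreversible,
    make_isomerases_reversible,
    standard_refinement,
)


class TestDecarboxylases:
    def test_fixture_ground_truth_set_affected(self, raw_core_bundle,
                                               raw_core_model):
        _, affected = make_decarboxylases_irreversible(raw_core_model)
        key = raw_core_bundle.ground_truth["refinement"]["decarboxylases"]
        assert affected == key

    def test_clamped_toward_co2_release(self, raw_core_model):
        make_decarboxylases_irreversible(raw_core_model)
        rxn = raw_core_model.reactions["PROPFERM"]
        assert rxn.lower_bound == 0.0 and rxn.upper_bound > 0
        assert rxn.stoichiometry["co2_c"] > 0  # forward releases CO2

    def test_atp_coupled_carboxylase_untouched(self, core_model):
        pc = core_model.reactions["PC"]
        before = (pc.lower_bound, pc.upper_bound)
        make_decarboxylases_irreversible(core_model)
        assert (pc.lower_bound, pc.upper_bound) == before

    def test_idempotent(self, raw_core_model):
        make_decarboxylases_irreversible(raw_core_model)
        _, affected = make_decarboxylases_irreversible(raw_core_model)
        assert affected == []

    def test_no_co2_fixation_into_biomass_without_atp_coupling(
            self, core_model):
        """After the decarboxylase rule, external CO2 only enters biomass
        carbon through ATP-coupled carboxylation: growth is independent of
        the CO2 uptake, and with the carboxylating ligase route disabled,
        opening CO2 cannot rescue growth."""
        base = qc.optimize(core_model, "BIOMASS", "max").objective_value
        closed = core_model.copy()
        closed.reactions["EX_co2_e"].lower_bound = 0.0
        no_co2 = qc.optimize(closed, "BIOMASS", "max").objective_value
        assert no_co2 == pytest.approx(base)
        for rid in ("PC", "ARGSYN"):  # the ATP-coupled carboxylation routes
            core_model.reactions[rid].upper_bound = 0.0
        rescued = qc.optimize(core_model, "BIOMASS", "max").objective_value
        assert rescued <= qc.ZERO_TOL


class TestIsomerases:
    def test_forward_only_isomerase_becomes_reversible(self, raw_core_model):
        assert raw_core_model.reactions["GLCMUTA"].lower_bound == 0.0
        _, affected = make_isomerases_reversible(raw_core_model)
        assert "GLCMUTA" in affected
        assert raw_core_model.reactions["GLCMUTA"].lower_bound == -math.inf

    def test_reaction_without_ec_unchanged(self, raw_core_model):
        gly1 = raw_core_model.reactions["GLY1"]
        before = (gly1.lower_bound, gly1.upper_bound)
        make_isomerases_reversible(raw_core_model)
        assert (gly1.lower_bound, gly1.upper_bound) == before

    def test_already_reversible_isomerase_unchanged(self, core_model):
        _, affected = make_isomerases_reversible(core_model)
        assert affected == []


class TestEnergyLeaks:
    def test_raw_fixture_has_unbounded_atp_yield(self, raw_core_model):
        with pytest.raises(qc.EnergyLeakError):
            qc.max_atp_yield(raw_core_model, "glc__D", aerobic=True)

    def test_fix_restores_finite_yield(self, raw_core_bundle, raw_core_model):
        ids = raw_core_bundle.ground_truth["refinement"]["energy_leaks"]
        fix_energy_leaks(raw_core_model, ids)
        value = qc.max_atp_yield(raw_core_model, "glc__D", aerobic=True)
        assert math.isfinite(value)

    def test_hydrolases_clamped_to_hydrolysis_direction(self, raw_core_model):
        fix_energy_leaks(raw_core_model, ["RXN_10862", "RXN-14218"])
        for rid in ("RXN_10862", "RXN-14218"):
            rxn = raw_core_model.reactions[rid]
            assert rxn.lower_bound == 0.0
            assert rxn.stoichiometry["pi_c"] > 0  # forward releases phosphate

    def test_id_matching_tolerates_hyphen_underscore_swap(self, raw_core_model):
        # the model spells them RXN_10862 / RXN-14218; the rule may not
        fix_energy_leaks(raw_core_model, ["RXN-10862", "RXN_14218"])
        assert raw_core_model.reactions["RXN_10862"].lower_bound == 0.0
        assert raw_core_model.reactions["RXN-14218"].lower_bound == 0.0

    def test_absent_id_warns_but_does_not_fail(self, raw_core_model, caplog):
        snapshot = {r: (x.lower_bound, x.upper_bound)
                    for r, x in raw_core_model.reactions.items()}
        with caplog.at_level("WARNING"):
            fix_energy_leaks(raw_core_model, ["NO-SUCH-RXN"])
        assert "NO-SUCH-RXN" in caplog.text
        assert snapshot == {r: (x.lower_bound, x.upper_bound)
                            for r, x in raw_core_model.reactions.items()}


class TestProtonSymport:
    def test_uniporters_become_symporters(self, raw_core_model):
        convert_to_proton_symport(raw_core_model, ["PYRt2m", "PIt2m"])
        pyrt = raw_core_model.reactions["PYRt2m"]
        assert pyrt.stoichiometry["h_c"] == Fraction(-1)
        assert pyrt.stoichiometry["h_m"] == Fraction(1)
        assert [e for e in check_balance(raw_core_model) if not e.skipped] == []

    def test_already_symport_unchanged(self, core_model):
        before = dict(core_model.reactions["PYRt2m"].stoichiometry)
        convert_to_proton_symport(core_model, ["PYRt2m"])
        assert dict(core_model.reactions["PYRt2m"].stoichiometry) == before

    def test_multi_cargo_transporter_rejected(self, raw_core_model):
        with pytest.raises(ModelError, match="exactly one"):
            convert_to_proton_symport(raw_core_model, ["ANT"])


class TestFullRefinement:
    def test_refining_raw_reproduces_refined_generator_output(
            self, raw_core_model, core_bundle):
        refined_ref = core_bundle.models["core_energy"]
        model, _ = standard_refinement(raw_core_model)
        for rid, ref in refined_ref.reactions.items():
            got = model.reactions[rid]
            assert (got.lower_bound, got.upper_bound) == (
                ref.lower_bound, ref.upper_bound), rid
            assert dict(got.stoichiometry) == dict(ref.stoichiometry), rid

    def test_refinement_preserves_balance(self, raw_core_model):
        before = [e.reaction_id for e in check_balance(raw_core_model)
                  if not e.skipped]
        model, _ = standard_refinement(raw_core_model)
        after = [e.reaction_id for e in check_balance(model) if not e.skipped]
        assert before == after == []

    def test_all_ops_idempotent(self, raw_core_model):
        model, _ = standard_refinement(raw_core_model)
        snapshot = {
            r: (x.lower_bound, x.upper_bound, dict(x.stoichiometry))
            for r, x in model.reactions.items()
        }
        model, _ = standard_refinement(model)
        assert snapshot == {
            r: (x.lower_bound, x.upper_bound, dict(x.stoichiometry))
            for r, x in model.reactions.items()
        }

    def test_no_free_energy_after_refinement(self, raw_core_model):
        model, _ = standard_refinement(raw_core_model)
        for ex in model.exchanges():
            ex.lower_bound = 0.0
        from wormflux.qc import _add_atp_demand, optimize

        demand = _add_atp_demand(model)
        sol = optimize(model, demand, "max")
        assert sol.optimal and abs(sol.objective_value) <= qc.ZERO_TOL


class TestDeclarativeRules:
    def test_rules_table_drives_the_same_refinement(self, raw_core_model,
                                                    core_bundle):
        rules = pd.DataFrame([
            {"selector_type": "stoichiometric_pattern",
             "selector_value": "decarboxylase",
             "action": "make_irreversible_forward"},
            {"selector_type": "ec_prefix", "selector_value": "5.",
             "action": "make_reversible"},
            {"selector_type": "reaction_id_list",
             "selector_value": "RXN_10862;RXN-14218",
             "action": "make_irreversible_forward"},
            {"selector_type": "reaction_id_list",
             "selector_value": "PYRt2m;PIt2m",
             "action": "proton_symport"},
        ])
        model, log = apply_rules(raw_core_model, rules)
        assert set(log["reaction_id"]) >= {"PROPFERM", "GLCMUTA", "RXN_10862"}
        ref = core_bundle.models["core_energy"]
        for rid in ("PROPFERM", "GLCMUTA", "RXN_10862", "RXN-14218"):
            assert (model.reactions[rid].lower_bound,
                    model.reactions[rid].upper_bound) == (
                ref.reactions[rid].lower_bound, ref.reactions[rid].upper_bound)

    def test_empty_rules_change_nothing(self, raw_core_model):
        rules = pd.DataFrame(columns=["selector_type", "selector_value", "action"])
        snapshot = {r: (x.lower_bound, x.upper_bound)
                    for r, x in raw_core_model.reactions.items()}
        model, log = apply_rules(raw_core_model, rules)
        assert len(log) == 0
        assert snapshot == {r: (x.lower_bound, x.upper_bound)
                            for r, x in model.reactions.items()}
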