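"""The LP physiology battery: optimize, blocked reactions (vs the cobrapy
oracle), ATP yields, P/O ratio, fermentation, essentiality and monomers."""

import math
import random
from fractions import Fraction

import pytest

from wormflux import qc
from wormflux.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)


def _linear_toy():
    """A -> B with capped input; hand-solved maximum is min(uptake, r1 cap)."""
    m = MetabolicModel(id="lp_toy", compartments={"c": "c"})
    for x in "AB":
        m.add_metabolite(Metabolite(f"{x}_c", compartment="c"))
    m.add_reaction(Reaction("EX_A", stoichiometry={"A_c": -1},
                            lower_bound=-5, upper_bound=0, flags={"exchange"}))
    m.add_reaction(Reaction("R1", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=3))
    m.add_reaction(Reaction("EX_B", stoichiometry={"B_c": -1},
                            lower_bound=0, upper_bound=math.inf,
                            flags={"exchange"}))
    return m


class TestOptimize:
    def test_toy_network_equals_hand_solution(self):
        m = _linear_toy()
        sol = qc.optimize(m, "R1", "max")
        assert sol.optimal and sol.objective_value == pytest.approx(3.0)
        # steady state holds and bounds are respected
        assert sol.fluxes["EX_A"] == pytest.approx(-3.0)
        assert sol.fluxes["EX_B"] == pytest.approx(3.0)
        sol_min = qc.optimize(m, "R1", "min")
        assert sol_min.objective_value == pytest.approx(0.0)

    def test_growth_positive_on_default_medium(self, core_model):
        sol = qc.optimize(core_model, "BIOMASS", "max")
        assert sol.optimal and sol.objective_value > 0.1

    def test_no_uptake_means_no_growth(self, core_model):
        for ex in core_model.exchanges():
            ex.lower_bound = 0.0
        sol = qc.optimize(core_model, "BIOMASS", "max")
        assert sol.status in ("optimal", "infeasible")
        if sol.optimal:
            assert sol.objective_value <= qc.ZERO_TOL

    def test_unknown_objective_rejected(self, core_model):
        with pytest.raises(ModelError):
            qc.optimize(core_model, "NOPE")


def _cobra_blocked_oracle(model, secretions=None):
    """Independent route: cobrapy + GLPK find_blocked_reactions."""
    from cobra.flux_analysis import find_blocked_reactions

    from wormflux.core import sanitize_id
    from wormflux.io import _to_cobra
    from wormflux.qc import _apply_exchange_policy

    clamped = _apply_exchange_policy(model, secretions)
    cm = _to_cobra(clamped)
    cm.solver = "glpk"
    back = {sanitize_id(r): r for r in clamped.reactions}
    return {back[r] for r in find_blocked_reactions(cm, open_exchanges=False)}


class TestBlockedReactions:
    @pytest.mark.parametrize(
        "model_fixture", ["small_core_model", "ump_model"]
    )
    def test_equals_exhaustive_two_lp_oracle(self, model_fixture, request):
        model = request.getfixturevalue(model_fixture)
        if model.biomass_reaction_id is None:
            model.biomass_reaction_id = None  # ump fixture: no biomass needed
        assert qc.blocked_reactions(model) == _cobra_blocked_oracle(model)

    def test_full_core_matches_generator_key(self, core_bundle, core_model):
        key = set(core_bundle.ground_truth["blocked_minimal_policy"])
        assert qc.blocked_reactions(core_model) == key

    def test_intentionally_dead_branch_blocked(self, core_model):
        # vitamin tokens are transported but consumed by nothing
        blocked = qc.blocked_reactions(core_model)
        assert {"THMt", "EX_thm_e"} <= blocked

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_under_medium_and_secretion_enlargement(
            self, seed, small_core_model):
        rng = random.Random(seed)
        model = small_core_model
        base_secretions = qc.minimal_secretion_ids(model)
        base = qc.blocked_reactions(model, secretions=base_secretions)

        enlarged = model.copy()
        closed = [ex.id for ex in model.exchanges()
                  if ex.id not in model.medium]
        extra_med = rng.sample(closed, min(3, len(closed)))
        for ex_id in extra_med:
            enlarged.medium[ex_id] = 10.0
        all_e_mets = sorted(
            met_id for r in model.exchanges() for met_id in r.stoichiometry)
        extra_sec = set(rng.sample(all_e_mets, min(4, len(all_e_mets))))
        bigger = qc.blocked_reactions(
            enlarged, secretions=base_secretions | extra_sec)
        assert bigger <= base

    def test_infeasible_base_model_directs_to_growth_check(self, core_model):
        core_model.reactions["BIOMASS"].lower_bound = 1e6  # force infeasibility
        with pytest.raises(qc.InfeasibleModelError, match="growth"):
            qc.blocked_reactions(core_model)


class TestAtpYield:
    def test_aerobic_34_anaerobic_2(self, core_model):
        assert qc.max_atp_yield(core_model, "glc__D", aerobic=True) == \
            pytest.approx(34.0)
        assert qc.max_atp_yield(core_model, "glc__D", aerobic=False) == \
            pytest.approx(2.0)

    def test_invariant_under_reaction_split(self, small_core_model):
        """Splitting a reaction in two via an intermediate does not change
        the optimum."""
        m = small_core_model
        baseline = qc.max_atp_yield(m, "glc__D", aerobic=True)
        gly1 = m.reactions["GLY1"]
        fdp = m.metabolites["fdp_c"]
        m.add_metabolite(Metabolite("fdp_pre_c", formula=fdp.formula,
                                    charge=fdp.charge, compartment="c"))
        stoich = dict(gly1.stoichiometry)
        stoich["fdp_pre_c"] = stoich.pop("fdp_c")
        gly1.stoichiometry = stoich
        m.add_reaction(Reaction("GLY1b", stoichiometry={
            "fdp_pre_c": Fraction(-1), "fdp_c": Fraction(1)},
            lower_bound=0, upper_bound=math.inf))
        assert qc.max_atp_yield(m, "glc__D", aerobic=True) == \
            pytest.approx(baseline)

    def test_invariant_under_reaction_reordering(self, small_core_model):
        baseline = qc.max_atp_yield(small_core_model, "glc__D", aerobic=True)
        items = list(small_core_model.reactions.items())
        random.Random(7).shuffle(items)
        small_core_model.reactions = dict(items)
        assert qc.max_atp_yield(small_core_model, "glc__D", aerobic=True) == \
            pytest.approx(baseline)

    def test_other_carbon_sources_closed(self, core_model):
        # amino-acid carbon must not inflate the glucose yield
        value = qc.max_atp_yield(core_model, "glc__D", aerobic=True)
        assert value == pytest.approx(34.0)

    def test_all_uptakes_closed_yields_zero(self, core_model):
        core_model.medium = {}
        for ex in core_model.exchanges():
            ex.lower_bound = 0.0
        from wormflux.qc import _add_atp_demand

        demand = _add_atp_demand(core_model)
        sol = qc.optimize(core_model, demand, "max")
        assert abs(sol.objective_value) <= qc.ZERO_TOL


class TestPoRatio:
    def test_default_chain_gives_2_5(self, core_model):
        assert qc.po_ratio(core_model) == pytest.approx(2.5)

    def test_scales_inversely_with_synthase_proton_cost(self):
        from wormflux.fixtures import make_core_energy_model

        halved = make_core_energy_model(
            p_o=1.25, synth_protons=8, include_biosynthesis=False)
        assert qc.po_ratio(halved.models["core_energy"]) == pytest.approx(1.25)

    def test_disabled_chain_is_an_error(self, small_core_model):
        chain = small_core_model.reactions["RESPCHAIN"]
        chain.lower_bound = chain.upper_bound = 0.0
        with pytest.raises(qc.InfeasibleModelError):
            qc.po_ratio(small_core_model)


class TestFermentation:
    def _anaerobic(self, model):
        from wormflux.qc import _oxygen_exchange

        m = model.copy()
        _oxygen_exchange(m).lower_bound = 0.0
        return m

    def test_lactate_2_per_glucose_and_all_five_products(self, core_model,
                                                         core_bundle):
        m = self._anaerobic(core_model)
        products = core_bundle.ground_truth["fermentation_products_producible"]
        profile = qc.fermentation_profile(m, "glc__D", products)
        assert profile["lac__L"] == pytest.approx(2.0)
        assert all(v > qc.ZERO_TOL for v in profile.values()), profile

    def test_open_o2_uptake_is_a_precondition_violation(self, core_model):
        with pytest.raises(ModelError, match="anaerobic"):
            qc.fermentation_profile(core_model, "glc__D", ["lac__L"])

    def test_absent_product_reports_zero(self, core_model):
        m = self._anaerobic(core_model)
        profile = qc.fermentation_profile(m, "glc__D", ["xyl__D"])
        assert profile["xyl__D"] == 0.0


class TestEssentiality:
    def test_matches_generator_key(self, core_bundle, core_model):
        key = set(core_bundle.ground_truth["essential_nutrients"])
        assert qc.nutrient_essentiality(core_model) == key

    def test_unused_vitamin_not_essential(self, core_model):
        essential = qc.nutrient_essentiality(core_model)
        assert "EX_thm_e" not in essential
        assert "EX_cbl1_e" not in essential

    def test_infeasible_base_medium_is_an_error(self, core_model):
        core_model.reactions["EX_glc__D_e"].lower_bound = 0.0
        del core_model.medium["EX_glc__D_e"]
        with pytest.raises(qc.InfeasibleModelError):
            qc.nutrient_essentiality(core_model)


class TestMonomerCatabolism:
    def test_matches_generator_key(self, core_bundle, core_model):
        key = core_bundle.ground_truth["monomer_catabolism"]
        assert qc.monomer_catabolism(core_model, sorted(key)) == key

    def test_beta_glucose_and_glcnac_metabolized(self, core_model):
        result = qc.monomer_catabolism(core_model, ["glc__bD", "acgam"])
        assert result == {"glc__bD": True, "acgam": True}


class TestReport:
    def test_full_battery_on_core_fixture(self, core_model, core_bundle):
        report = qc.run_qc(
            core_model,
            fermentation_products=core_bundle.ground_truth[
                "fermentation_products_producible"],
            monomers=["glc__bD", "acgam"],
        )
        assert report.grows
        assert report.atp_per_glucose == pytest.approx(34.0)
        assert report.po_ratio == pytest.approx(2.5)
        assert report.n_blocked == len(report.blocked)
        payload = report.to_dict()
        assert payload["monomer_catabolism"]["acgam"] is True

    def test_infeasible_model_reports_no_growth_without_crashing(self,
                                                                 core_model):
        core_model.reactions["EX_asn__L_e"].lower_bound = 0.0
        del core_model.medium["EX_asn__L_e"]
        report = qc.run_qc(core_model)
        assert report.grows is False
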