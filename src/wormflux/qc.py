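"""LP-based physiology battery: growth, blocked reactions, ATP yield, P/O
ratio, fermentation profile, nutrient essentiality and monomer catabolism.

All operations reduce to steady-state flux LPs

    maximize c^T v   subject to   S v = 0,   lb <= v <= ub,

solved in double precision with HiGHS (scipy.optimize.linprog).  Vertex
selection may differ between solvers; every quantity reported here is an
optimal *objective value*, which is unique.  "Zero" flux means |v| < 1e-9
throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    FLAG_EXCHANGE,
    MetabolicModel,
    ModelError,
    Reaction,
)

__all__ = [
    "FluxSolution",
    "QCReport",
    "EnergyLeakError",
    "optimize",
    "blocked_reactions",
    "max_atp_yield",
    "po_ratio",
    "fermentation_profile",
    "nutrient_essentiality",
    "monomer_catabolism",
    "minimal_secretion_ids",
    "run_qc",
]

ZERO_TOL = 1e-9


class EnergyLeakError(RuntimeError):
    """An ATP-yield LP is unbounded: the network regenerates ATP for free."""


class InfeasibleModelError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class _LP:
    """Stoichiometric LP over a model; objective can be swapped cheaply."""

    def __init__(self, model: MetabolicModel):
        self.rxn_ids = list(model.reactions)
        self.met_index = {m: i for i, m in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.rxn_ids):
            for mid, coeff in model.reactions[rid].stoichiometry.items():
                rows.append(self.met_index[mid])
                cols.append(j)
                vals.append(float(coeff))
        n_m, n_r = len(self.met_index), len(self.rxn_ids)
        self.S = sparse.coo_matrix((vals, (rows, cols)), shape=(n_m, n_r)).tocsc()
        self.bounds = []
        for rid in self.rxn_ids:
            rxn = model.reactions[rid]
            lb = None if rxn.lower_bound == -math.inf else float(rxn.lower_bound)
            ub = None if rxn.upper_bound == math.inf else float(rxn.upper_bound)
            self.bounds.append((lb, ub))
        self.rxn_index = {r: j for j, r in enumerate(self.rxn_ids)}

    def solve(self, objective_id: str, direction: str = "max") -> FluxSolution:
        if objective_id not in self.rxn_index:
            raise ModelError(f"objective reaction {objective_id!r} not in model")
        if direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")
        c = np.zeros(len(self.rxn_ids))
        sign = -1.0 if direction == "max" else 1.0
        c[self.rxn_index[objective_id]] = sign
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=self.bounds,
            method="highs",
        )
        if res.status == 0:
            fluxes = dict(zip(self.rxn_ids, res.x))
            return FluxSolution(sign * res.fun, fluxes, "optimal")
        if res.status == 2:
            return FluxSolution(None, {}, "infeasible")
        if res.status == 3:
            return FluxSolution(math.inf if direction == "max" else -math.inf,
                                {}, "unbounded")
        return FluxSolution(None, {}, f"solver_error_{res.status}")


def optimize(
    model: MetabolicModel, objective_reaction_id: str, direction: str = "max"
) -> FluxSolution:
    """Solve the steady-state flux LP for one objective reaction."""
    return _LP(model).solve(objective_reaction_id, direction)


# --- bound policies ----------------------------------------------------------


def minimal_secretion_ids(model: MetabolicModel) -> set[str]:
    """Metabolite ids of the minimal inorganic secretion set: CO2, water and
    free protons (identified by formula, not by name), wherever they have an
    exchange reaction."""
    allowed = set()
    for rxn in model.exchanges():
        (met_id,) = rxn.stoichiometry
        met = model.metabolites[met_id]
        if met.formula is None or met.charge is None:
            continue
        counts = dict(met.formula.items())
        if (counts, met.charge) in (
            ({"C": 1, "O": 2}, 0),
            ({"H": 2, "O": 1}, 0),
            ({"H": 1}, 1),
        ):
            allowed.add(met_id)
    return allowed


def _apply_exchange_policy(
    model: MetabolicModel, secretions: set[str] | None
) -> MetabolicModel:
    """Copy of the model with uptakes per the medium and secretion restricted
    to ``secretions`` (None = the minimal CO2/H2O/H+ policy)."""
    clamped = model.copy()
    if secretions is None:
        secretions = minimal_secretion_ids(clamped)
    for rxn in clamped.exchanges():
        rxn.lower_bound = -clamped.medium.get(rxn.id, 0.0)
        (met_id,) = rxn.stoichiometry
        rxn.upper_bound = math.inf if met_id in secretions else 0.0
    return clamped


def _close_carbon_uptakes(model: MetabolicModel, keep: set[str]) -> None:
    """Shut the inflow of every exchange whose metabolite contains carbon,
    except the exchanges listed in ``keep``."""
    for rxn in model.exchanges():
        if rxn.id in keep:
            continue
        (met_id,) = rxn.stoichiometry
        met = model.metabolites[met_id]
        if met.formula is not None and met.formula.get("C") > 0:
            rxn.lower_bound = 0.0


def _oxygen_exchange(model: MetabolicModel) -> Reaction | None:
    for rxn in model.exchanges():
        (met_id,) = rxn.stoichiometry
        met = model.metabolites[met_id]
        if met.formula is not None and dict(met.formula.items()) == {"O": 2} \
                and met.charge == 0:
            return rxn
    return None


def _resolve_exchange(model: MetabolicModel, ref: str) -> Reaction | None:
    """Accept an exchange-reaction id, a metabolite id, or a compartment-free
    base id and return the exchange reaction, if any."""
    rxn = model.reactions.get(ref)
    if rxn is not None and FLAG_EXCHANGE in rxn.flags:
        return rxn
    if ref in model.metabolites:
        return model.exchange_for(ref)
    for cand in model.exchanges():
        (met_id,) = cand.stoichiometry
        if model.metabolites[met_id].base_id() == ref:
            return cand
    return None


ATP_DEMAND_ID = "DM_atp_hydrolysis"


def _add_atp_demand(model: MetabolicModel, compartment: str = "c") -> str:
    """Install the ATP-hydrolysis demand ATP + H2O -> ADP + Pi + H+ used for
    yield computations; returns its reaction id."""
    if ATP_DEMAND_ID in model.reactions:
        return ATP_DEMAND_ID
    species = {}
    for base in ("atp", "adp", "pi", "h", "h2o"):
        met = model.find_metabolite(base, compartment)
        if met is None:
            raise ModelError(
                f"cannot locate {base!r} in {compartment!r} for the ATP demand"
            )
        species[base] = met.id
    rxn = Reaction(
        id=ATP_DEMAND_ID,
        name="ATP hydrolysis demand",
        stoichiometry={
            species["atp"]: Fraction(-1),
            species["h2o"]: Fraction(-1),
            species["adp"]: Fraction(1),
            species["pi"]: Fraction(1),
            species["h"]: Fraction(1),
        },
        lower_bound=0.0,
        upper_bound=math.inf,
    )
    model.add_reaction(rxn)
    return ATP_DEMAND_ID


# --- the battery -------------------------------------------------------------


def blocked_reactions(
    model: MetabolicModel,
    secretions: set[str] | None = None,
    tolerance: float = ZERO_TOL,
) -> set[str]:
    """Reactions that cannot carry flux when only biomass production with the
    model's medium is enabled.

    Uptake follows the medium, secretion the policy (default: the minimal
    CO2/water/proton set), biomass is free.  A reaction is blocked iff both
    its maximal and minimal achievable fluxes are zero within tolerance —
    the flux-variability definition.
    """
    clamped = _apply_exchange_policy(model, secretions)
    lp = _LP(clamped)
    if model.biomass_reaction_id:
        probe = lp.solve(model.biomass_reaction_id, "max")
        if probe.status == "infeasible":
            raise InfeasibleModelError(
                "base model infeasible under the blocked-reaction policy; "
                "check growth (medium/biomass) first"
            )
    blocked = set()
    for rid in lp.rxn_ids:
        vmax = lp.solve(rid, "max")
        if vmax.status == "unbounded" or (
            vmax.optimal and vmax.objective_value > tolerance
        ):
            continue
        vmin = lp.solve(rid, "min")
        if vmin.status == "unbounded" or (
            vmin.optimal and vmin.objective_value < -tolerance
        ):
            continue
        blocked.add(rid)
    return blocked


def max_atp_yield(
    model: MetabolicModel,
    substrate_exchange: str,
    aerobic: bool = True,
    demand_compartment: str = "c",
) -> float:
    """Maximal ATP-hydrolysis flux at substrate uptake 1.

    All other carbon uptakes are closed; the O2 exchange opens iff aerobic.
    Raises :class:`EnergyLeakError` when the LP is unbounded (free ATP
    regeneration, see the reversibility refiner).
    """
    work = model.copy()
    sub = _resolve_exchange(work, substrate_exchange)
    if sub is None:
        raise ModelError(f"no exchange for substrate {substrate_exchange!r}")
    _close_carbon_uptakes(work, keep={sub.id})
    sub.lower_bound = -1.0
    sub.upper_bound = min(sub.upper_bound, 0.0)
    o2 = _oxygen_exchange(work)
    if o2 is not None:
        o2.lower_bound = -math.inf if aerobic else 0.0
    elif aerobic:
        raise ModelError("no O2 exchange found for an aerobic yield")
    demand = _add_atp_demand(work, demand_compartment)
    sol = optimize(work, demand, "max")
    if sol.status == "unbounded":
        raise EnergyLeakError(
            "ATP yield unbounded: the network contains a free ATP-regeneration "
            "loop (apply fix_energy_leaks)"
        )
    if not sol.optimal:
        raise InfeasibleModelError(f"ATP-yield LP ended with status {sol.status}")
    return float(sol.objective_value)


def po_ratio(
    model: MetabolicModel,
    donor_couple: tuple[str, str] = ("nadh_m", "nad_m"),
    demand_compartment: str = "c",
) -> float:
    """ATP synthesized per oxygen *atom* reduced, with the reduced carrier
    supplied at rate 1 as the sole electron donor.

    A temporary regeneration reaction (oxidized + H+ -> reduced) runs at a
    fixed rate of 1; all carbon uptakes are closed; the ATP-hydrolysis demand
    is maximized; P/O = ATP flux / (2 x O2 uptake flux).
    """
    reduced_id, oxidized_id = donor_couple
    work = model.copy()
    for mid in donor_couple:
        if mid not in work.metabolites:
            raise ModelError(f"donor-couple species {mid!r} not in model")
    comp = work.metabolites[reduced_id].compartment
    h = work.find_metabolite("h", comp)
    if h is None:
        raise ModelError(f"no free proton species in compartment {comp!r}")
    _close_carbon_uptakes(work, keep=set())
    regen = Reaction(
        id="TMP_carrier_regeneration",
        name="carrier regeneration (pseudo)",
        stoichiometry={
            oxidized_id: Fraction(-1),
            h.id: Fraction(-1),
            reduced_id: Fraction(1),
        },
        lower_bound=1.0,
        upper_bound=1.0,
    )
    work.add_reaction(regen)
    o2 = _oxygen_exchange(work)
    if o2 is None:
        raise ModelError("no O2 exchange: respiration impossible")
    o2.lower_bound = -math.inf
    demand = _add_atp_demand(work, demand_compartment)
    sol = optimize(work, demand, "max")
    if not sol.optimal or sol.objective_value <= ZERO_TOL:
        raise InfeasibleModelError(
            "no feasible respiration: cannot oxidize the supplied carrier "
            f"(status {sol.status})"
        )
    o2_uptake = -sol.fluxes[o2.id]
    if o2_uptake <= ZERO_TOL:
        raise InfeasibleModelError("carrier oxidized without O2 consumption")
    return float(sol.objective_value / (2.0 * o2_uptake))


def fermentation_profile(
    model: MetabolicModel,
    substrate_exchange: str,
    products: list[str],
) -> dict[str, float]:
    """Maximal anaerobic secretion of each product at substrate uptake 1.

    Precondition: the O2 exchange is closed for uptake.  Each product's
    secretion is opened and maximized independently; a strictly positive
    value means the product is producible.
    """
    o2 = _oxygen_exchange(model)
    if o2 is not None and o2.lower_bound < 0:
        raise ModelError(
            "fermentation profile requires anaerobic conditions: close the O2 "
            "uptake first"
        )
    work = model.copy()
    sub = _resolve_exchange(work, substrate_exchange)
    if sub is None:
        raise ModelError(f"no exchange for substrate {substrate_exchange!r}")
    sub.lower_bound = -1.0
    sub.upper_bound = min(sub.upper_bound, 0.0)
    profile: dict[str, float] = {}
    for product in products:
        ex = _resolve_exchange(work, product)
        if ex is None:
            profile[product] = 0.0
            continue
        old_ub = ex.upper_bound
        ex.upper_bound = math.inf
        sol = optimize(work, ex.id, "max")
        ex.upper_bound = old_ub
        profile[product] = float(sol.objective_value) if sol.optimal else 0.0
    return profile


def nutrient_essentiality(
    model: MetabolicModel, tolerance: float = ZERO_TOL
) -> set[str]:
    """Medium entries whose removal abolishes growth.

    Requires feasible growth on the full medium."""
    if not model.biomass_reaction_id:
        raise ModelError("model has no biomass objective")
    work = model.copy()
    lp = _LP(work)
    base = lp.solve(work.biomass_reaction_id, "max")
    if not base.optimal or base.objective_value <= tolerance:
        raise InfeasibleModelError(
            "growth on the full medium is infeasible; essentiality undefined"
        )
    essential = set()
    for ex_id in sorted(work.medium):
        rxn = work.reactions[ex_id]
        old = rxn.lower_bound
        rxn.lower_bound = 0.0
        sol = _LP(work).solve(work.biomass_reaction_id, "max")
        rxn.lower_bound = old
        if not sol.optimal or sol.objective_value < tolerance:
            essential.add(ex_id)
    return essential


def monomer_catabolism(
    model: MetabolicModel,
    monomers: list[str],
    demand_compartment: str = "c",
) -> dict[str, bool]:
    """Can each monomer, as sole carbon source at uptake 1, yield ATP?"""
    result: dict[str, bool] = {}
    for monomer in monomers:
        ex = _resolve_exchange(model, monomer)
        if ex is None:
            result[monomer] = False
            continue
        try:
            yield_ = max_atp_yield(model, ex.id, aerobic=True,
                                   demand_compartment=demand_compartment)
        except (EnergyLeakError, InfeasibleModelError, ModelError):
            result[monomer] = False
            continue
        result[monomer] = yield_ > ZERO_TOL
    return result


# --- aggregate report --------------------------------------------------------


@dataclass
class QCReport:
    grows: bool
    growth_value: float
    blocked: set[str]
    atp_per_glucose: float | None
    po_ratio: float | None
    fermentation: dict[str, float]
    essential_nutrients: set[str]
    monomer_catabolism: dict[str, bool]
    notes: list[str] = field(default_factory=list)

    @property
    def n_blocked(self) -> int:
        return len(self.blocked)

    def to_dict(self) -> dict:
        return {
            "grows": self.grows,
            "growth_value": self.growth_value,
            "n_blocked": self.n_blocked,
            "blocked": sorted(self.blocked),
            "atp_per_glucose": self.atp_per_glucose,
            "po_ratio": self.po_ratio,
            "fermentation": self.fermentation,
            "essential_nutrients": sorted(self.essential_nutrients),
            "monomer_catabolism": self.monomer_catabolism,
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_qc(
    model: MetabolicModel,
    glucose_exchange: str | None = "glc__D",
    donor_couple: tuple[str, str] = ("nadh_m", "nad_m"),
    fermentation_products: list[str] | None = None,
    monomers: list[str] | None = None,
    secretions: set[str] | None = None,
) -> QCReport:
    """Run the full physiology battery and collect a report.

    Individual probes that error (e.g. no respiratory chain) are recorded as
    notes rather than aborting the battery: QC findings are data.
    """
    notes: list[str] = []
    growth_value = 0.0
    grows = False
    if model.biomass_reaction_id:
        sol = optimize(model, model.biomass_reaction_id, "max")
        if sol.optimal:
            growth_value = float(sol.objective_value)
            grows = growth_value > ZERO_TOL
        else:
            notes.append(f"growth LP status: {sol.status}")
    else:
        notes.append("no biomass objective")

    try:
        blocked = blocked_reactions(model, secretions=secretions)
    except InfeasibleModelError as exc:
        blocked = set()
        notes.append(str(exc))

    atp = pore = None
    if glucose_exchange is not None:
        try:
            atp = max_atp_yield(model, glucose_exchange, aerobic=True)
        except (EnergyLeakError, InfeasibleModelError, ModelError) as exc:
            notes.append(f"atp_per_glucose: {exc}")
    try:
        pore = po_ratio(model, donor_couple)
    except (InfeasibleModelError, ModelError) as exc:
        notes.append(f"po_ratio: {exc}")

    fermentation: dict[str, float] = {}
    if fermentation_products and glucose_exchange is not None:
        anaerobic = model.copy()
        o2 = _oxygen_exchange(anaerobic)
        if o2 is not None:
            o2.lower_bound = 0.0
        try:
            fermentation = fermentation_profile(
                anaerobic, glucose_exchange, fermentation_products
            )
        except ModelError as exc:
            notes.append(f"fermentation: {exc}")

    try:
        essential = nutrient_essentiality(model)
    except (InfeasibleModelError, ModelError) as exc:
        essential = set()
        notes.append(f"essentiality: {exc}")

    monomer = monomer_catabolism(model, monomers) if monomers else {}

    return QCReport(
        grows=grows,
        growth_value=growth_value,
        blocked=blocked,
        atp_per_glucose=atp,
        po_ratio=pore,
        fermentation=fermentation,
        essential_nutrients=essential,
        monomer_catabolism=monomer,
        notes=notes,
    )
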