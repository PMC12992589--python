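# Methods

`wormflux` implements the post-annotation stage of building a
compartmentalized eukaryotic genome-scale metabolic model: a *flat* draft
(the shape a pathway-database export has — most reactions cytosolic, no
inter-compartment transporters) is mapped onto an already-compartmentalized
*template* model of a related organism, compartment assignments and
mitochondrion/cytosol transporters are transferred, a small set of targeted
curations is applied, and the result is screened with an LP-based
physiology battery.

## The constraint-based formalism

All quantitative checks are flux balance analysis: over steady-state flux
vectors `v` with stoichiometric matrix `S`,

    maximize c'v   subject to   S v = 0,   lb <= v <= ub.

LPs are solved in double precision with HiGHS (`scipy.optimize.linprog`).
Only optimal *objective values* are reported — they are unique, while the
optimal vertex is not. "Zero flux" means `|v| < 1e-9` everywhere.
Stoichiometric coefficients are exact rationals (`fractions.Fraction`)
in memory and decimal doubles in SBML; bounds are floats and may be
infinite.

## Protonation-tolerant identifier matching

Two reference biochemistries may store the same metabolite in different
protonation states, so formula/charge equality is too strict and identifier
links alone are too loose. A candidate pair `(a, b)` from the
cross-reference graph is **verified** iff

    formula_a \ {H} = formula_b \ {H}   and   H_b − H_a = q_b − q_a ,

i.e. the hydrogen-count difference is exactly the charge difference (a pure
protonation shift); the signed difference is recorded as the proton delta.
Species with unknown formula or charge are never silently matched. Water is
*not* stripped in reaction comparison — only free protons (formula `H`,
charge +1) are, because only proton-balance differences are tolerated.
Reactions are compared as compartment-agnostic, proton-stripped coefficient
multisets, equal (same direction) or equal after negation (reversed); the
coefficients must be equal, not merely proportional (a config switch exists
but defaults to off — proportional matching invites false positives).

Candidate pairs come from a graph over `(namespace, identifier)` nodes with
edge provenance `manual > direct_link > bridge_table > shared_third_party`
(that order breaks selection ties, then lexicographic template id). Bridge
registry entries and shared third-party annotations are collapsed to edges
at build time; paths are never chased beyond one intermediate third-party
node, because transitive closure over noisy cross-references drifts.

## Compartment transfer and transporter grafting

For each source reaction, in priority order: an explicit mitochondrial
designation keeps the source compartments; a manual table entry wins over a
template transfer; a reaction match adopts the template counterpart's
(single, non-extracellular) compartment; anything else stays cytosolic and
is reported as unresolved. A template counterpart spanning cytosol *and*
mitochondrion is a transporter and never a relocation target — such
reactions are instead grafted: whenever every transported species has a
verified match into the source namespace and exists in the source model,
the template transporter is copied (source species instances created on
demand, stoichiometry and bounds kept, duplicates skipped). Relocation only
moves a reaction's cytosolic species; membrane-spanning source reactions
are never split. Both operations are idempotent and cannot change the
mass/charge balance report, since instances copy formula and charge.

## Curation operations

* **Biomass + GAM** — the biomass reaction consumes the declared components
  plus `gam` ATP and water and releases `gam` ADP, phosphate and protons
  (the hydrolysis water/proton bookkeeping is included to keep the equation
  interpretable; biomass is excluded from balance checking regardless).
  Default `gam` = 20 ATP-equivalents per unit biomass, a lower-limit value.
* **Medium** — uptake caps on exchanges keyed by extracellular metabolite;
  all other uptakes close; secretion opens exactly for the model's allowed-
  secretion set. Media and secretion policy round-trip through exchange
  bounds in SBML.
* **Quinone-coupled enzyme relocation** — the reaction's electron-acceptor
  couple (the reactant/product pair gaining 2 H at equal coefficient) is
  replaced by the mitochondrial quinone/quinol couple and the remaining
  participants move to the intermembrane space `i`. If the replacement
  would unbalance the reaction, the model is left untouched and an error
  raised.
* **Intermembrane shuttles** — reversible, gene-less `c <-> i` transporters;
  technical reactions justified by the outer membrane's permeability to
  small molecules. Together with the relocation this makes an
  inner-membrane-linked pathway (the UMP fixture's dihydroorotate
  dehydrogenase) operational.

## Reversibility rules

* Decarboxylases become irreversible toward CO2 release. Detection is by EC
  class 4.1.1 where EC data exist, with a stoichiometric fallback for
  EC-less reactions: currently reversible, releases free CO2, and carries
  no energy coupling (no participant with >= 2 phosphorus atoms — this
  exempts nucleotide- and NAD(P)/CoA-coupled chemistry such as reductive
  carboxylation). Carboxylating ligases (EC 6.4.1) and transport/boundary
  reactions are never touched. The clamped direction is read from the
  stoichiometry (which side CO2 sits on), never from the stored writing
  direction, which is arbitrary in exports.
* Isomerases (EC 5.-) get symmetric bounds.
* Named hydrolases are clamped to the phosphate-releasing direction; id
  lookup unescapes and treats `-`/`_` as interchangeable, since database
  identifiers appear in both spellings. This removes free ATP-regeneration
  loops (a reversible hydrolase plus the ATP demand is an unbounded
  two-cycle).
* Selected `c <-> m` uniporters become proton symporters: one proton per
  cargo molecule co-moves in the cargo direction, which preserves balance by
  construction. A transporter moving more than one cargo species is an
  error.

All four rule families are idempotent and balance-preserving.

## The QC battery

* **Growth** — biomass maximum under the installed medium.
* **Blocked reactions** — a reaction is blocked iff both its maximal and
  minimal flux are zero (two signed LPs per reaction, the flux-variability
  definition) when uptake follows the medium, biomass is free, and
  secretion is restricted to a policy set. The default policy is the
  minimal inorganic set {CO2, H2O, H+} (identified by formula, not name):
  a strictly biomass-only policy would make respiration itself infeasible,
  and this is the weakest relaxation. The policy is an argument, because
  enlarging the medium or the secretion set can only shrink the blocked set
  (monotonicity, tested).
* **ATP yield** — substrate uptake fixed to 1, every other carbon uptake
  closed, O2 open iff aerobic, and a temporary ATP-hydrolysis demand
  (ATP + H2O -> ADP + Pi + H+) maximized. An unbounded LP is reported as an
  energy leak, pointing at the hydrolase rule.
* **P/O ratio** — per oxygen *atom* (the biochemical convention): a
  pseudo-reaction regenerates the reduced carrier at rate 1 as sole
  electron donor, carbon uptakes closed, and P/O = max ATP flux divided by
  twice the O2 uptake flux.
* **Fermentation profile** — anaerobic (O2 uptake must already be closed,
  otherwise a precondition error), substrate at 1; each product's secretion
  is opened and maximized independently; producible means > 1e-9.
* **Nutrient essentiality** — a medium entry is essential iff closing its
  uptake drops the biomass optimum below 1e-9 (growth on the full medium
  must be feasible first).
* **Monomer catabolism** — the monomer as sole carbon source at uptake 1;
  metabolized iff the ATP demand optimum is positive.

## The synthetic fixtures

The generators produce the study conditions for every test; all fixture
models are exactly mass- and charge-balanced with real elemental formulas
(BiGG-style, pH-7 protonation states), asserted at construction.

**Core-energy fixture** (115 reactions full, 50 in the oracle-sized
variant). Glycolysis is lumped to three reactions with the textbook net
equation (2 ATP + 2 NADH per glucose); PDH plus a lumped TCA give, per
pyruvate, 5 carrier-H2 and 1 GTP; the respiratory chain pumps 10 protons
per NADH with 1/2 O2 and the synthase consumes 4 intermembrane protons per
ATP. All reducing equivalents are routed through the single NADH pool so
that one P/O figure (10/4 = 2.5) governs the whole yield — a deliberate
simplification, distinct from the textbook 2.5/1.5 split between NADH- and
FADH2-linked electrons — giving aerobically 2 + 2 + 12 x 2.5 = 34 ATP per
glucose and anaerobically 2. Both chain stoichiometries are parameters; any
P/O expressible as (integer <= 20)/synthase-protons is constructible.
Three proton-bookkeeping conventions make the stoichiometry close: the
matrix-facing chain/synthase proton counts include the chemical protons, an
electroneutral `c -> m` proton re-entry lump balances the carriers (it
cannot reach the intermembrane pool, so it cannot shortcut ATP synthesis),
and free protons are exchangeable with the environment. Fermentation
branches produce lactate, alanine (via transamination + glutamate
dehydrogenase), acetate, succinate (reductive carboxylation — CO2 uptake is
part of the medium, as bicarbonate is in any physiological milieu; without
it succinate export is electron-infeasible from glucose alone) and
propionate (a decarboxylase, reversible in the raw variant). The full
variant adds lumped biosynthesis of the ten non-essential amino acids, two
fatty acids, and eight DNA/RNA precursor tokens whose placeholder
compositions are derived as the residual of their declared synthesis lump
(balanced by construction); the biomass is the 20 proteinogenic amino acids
at equal weight, the 8 tokens, palmitate and oleate, with GAM 20. The
medium is glucose plus the nine metazoan-essential amino acids, asparagine,
six vitamin tokens (transported but unused — intentional dead branches),
and an inorganic base (O2, CO2, water, protons, ammonium, phosphate,
sulfate), uptake 10 (inorganics effectively unlimited). There is no
asparagine synthase, so asparagine is essential by construction. The raw
variant differs exactly by the four reversibility-rule targets
(reversible ATP/dGDP hydrolases, reversible propionate decarboxylase,
forward-only anomer isomerase, uniporter carriers).

**Mapping fixture** — seeded random species pairs with planted protonation
shifts (accepted), dH != dq decoys (rejected), one formula conflict, three
provenance routes, and reactions whose template side compensates planted
shifts with free-proton terms, as real paired biochemistries do.

**Template pair** — a flat BioCyc-style source and a compartmentalized
BiGG-style template covering relocation, designation, manual override, an
unmappable acyl-carrier reaction, graftable transporters and one skipped
one, and a protonation-shifted succinate.

**UMP fixture** — the de-novo pyrimidine pathway with its dehydrogenase
written cytosolically against an unregenerated quinone couple (infeasible),
repaired by the relocation + shuttle pair; an optional uracil-salvage
variant is feasible regardless.

What the fixtures do **not** emulate: the size of real models (~1500
metabolites), gene–protein–reaction rules, annotation noise and missing
formulas at scale, multi-compartment template reactions beyond
transporters, and the exact deposited medium/secretion configuration behind
the published blocked-reaction counts. Passing tests therefore demonstrate
correctness of the operations on declared ground truth, not
field-readiness against arbitrary exports.

## Answer keys and oracles

Every fixture ships a ground-truth key; tests consume keys rather than
recomputing expectations with the code under test. Where a key is itself a
computation (the blocked set, nutrient essentiality), it is produced at
generation time through an independent route — cobrapy with GLPK — and the
test compares `wormflux`'s scipy/HiGHS implementation against it. Matching
is additionally checked against a brute-force all-pairs comparator written
in plain dict arithmetic.

## Problem sizes

The default test run uses the 115-reaction core fixture, its 50-reaction
variant for exhaustive per-reaction LP oracles, 20 seeds of the mapping
fixture, 10 randomized medium/secretion enlargements for monotonicity, and
random 10-reaction networks for the dead-end pruning oracle; the whole
suite is a few hundred small LPs and finishes in well under a minute.

## Known limitations

No thermodynamic (dG) direction assignment and no loop-law MILP; flux
bounds are the only directionality mechanism. Identifier escaping is
reversible but cannot distinguish a raw id that already contains an escape
sequence. Compartment transfer adopts only single-compartment template
assignments; genuinely multi-compartment template chemistry (beyond c<->m
transporters) is left unresolved for manual assignment. Gene associations
are carried through I/O but unused by the analyses (no gene-essentiality
data exist for these organisms).
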