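# wormflux

Toolkit for turning a *flat* eukaryotic metabolic-model draft (the shape a
pathway-database export has: everything cytosolic, no transporters) into a
compartmentalized, growth-capable genome-scale model, and for verifying its
physiology. It was built around the reconstruction workflow for earthworm
(*Lumbricus*) models compartmentalized against a *C. elegans* template, but
every operation is generic: it is aimed at anyone mapping a BioCyc-style
draft onto a BiGG-style template model.

The pipeline:

1. **Cross-namespace mapping** (`wormflux.xref`) — metabolites are matched
   through an identifier graph (direct links, bridge registries such as
   MetaNetX, shared third-party ids such as KEGG) and every candidate pair
   is chemically verified with the *protonation-tolerance* rule: accepted
   iff all non-hydrogen element counts agree and ΔH = Δcharge. Reactions
   match when their proton-stripped, compartment-agnostic stoichiometries
   coincide (either direction).
2. **Compartmentalization** (`wormflux.compartmentalize`) — matched
   reactions adopt the template's compartment; explicitly mitochondrial
   reactions stay put; manual assignments override; the template's
   mitochondrion/cytosol transporters are grafted wherever their species
   exist in the source.
3. **Curation** (`wormflux.curation`) — biomass with growth-associated
   maintenance (GAM), medium installation, relocation of quinone-coupled
   enzymes to the inner mitochondrial membrane, and technical
   outer-membrane shuttles.
4. **Reversibility refinement** (`wormflux.reversibility`) — decarboxylases
   irreversible toward CO2 release, isomerases reversible, named hydrolases
   clamped to hydrolysis (kills free ATP-regeneration loops), mitochondrial
   carriers as proton symporters.
5. **Physiology QC** (`wormflux.qc`) — flux balance analysis
   (max c'v s.t. Sv = 0, lb ≤ v ≤ ub): growth, blocked reactions
   (FVA: max |v| = 0 under medium + minimal secretion policy), maximal ATP
   yield per substrate, P/O ratio per oxygen atom
   (v_ATP / (2·v_O2)), anaerobic fermentation profile, nutrient
   essentiality, and monomer catabolism.

Models are SBML Level 3 + FBC (read/written via cobrapy); stoichiometry is
held as exact rationals; synthetic, fully mass/charge-balanced fixtures
with ground-truth answer keys live in `wormflux.fixtures`.

## Worked example

Generate the core-energy fixture — a compact eukaryotic energy metabolism
whose respiratory chain pumps 10 protons per electron pair and whose ATP
synthase costs 4 protons per ATP — and run the QC battery on it:

```sh
wormflux fixtures --kind core_energy --seed 1 --outdir demo
wormflux qc --model demo/core_energy.xml --out demo/report.json
```

The report contains (abridged):

```json
{
 "grows": true,
 "growth_value": 0.20833333333333334,
 "atp_per_glucose": 34.0,
 "po_ratio": 2.5,
 "n_blocked": 35,
 "fermentation": {"ac": 0.667, "ala__L": 2.0, "lac__L": 2.0,
                  "ppa": 1.333, "succ": 1.333},
 "essential_nutrients": ["EX_asn__L_e", "EX_glc__D_e", "EX_his__L_e", "..."],
 "monomer_catabolism": {"acgam": true, "glc__bD": true}
}
```

Reading the numbers: complete aerobic oxidation of one glucose yields
**34 ATP** (2 glycolytic ATP + 2 GTP + 12 electron pairs × P/O 2.5), the
chain's **P/O ratio is 2.5** ATP per oxygen atom, all five invertebrate
fermentation products (lactate, succinate, alanine, acetate, propionate)
are producible anaerobically, both the cellulase monomer (β-glucose) and
the chitinase monomer (N-acetyl-D-glucosamine) support ATP production as
sole carbon source, and asparagine is an essential nutrient because the
network carries an asparaginase but no asparagine synthase. The 35 blocked
reactions are the vitamin-token dead branches plus the fermentation
machinery, which cannot run when secretion is restricted to the minimal
CO2/water/proton policy used for blocked-reaction counting.

The mapping/compartmentalization stages have the same shape:
`wormflux fixtures --kind template_pair`, then `wormflux map` and
`wormflux compartmentalize` on the emitted files; each writes TSV reports
that can be compared with the bundle's `ground_truth.json`.

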