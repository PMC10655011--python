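# Methods

## Model representation and conventions

A model is a list of compartmentalized metabolites (`_c` cytosol, `_m`
mitochondrion, `_p` plastid, `_x` peroxisome, `_v` vacuole) and
reactions with bounds and boolean gene rules. Three conventions are
load-bearing:

* **Import-positive exchanges.** Exchange reactions (`*_Cyto_tx`) have a
  single metabolite with coefficient +1; positive flux is uptake and the
  upper bound encodes availability. External pools are not rows of the
  stoichiometric matrix, so exchanges are the only unbalanced columns.
* **Cytosol hub.** Every transport reaction spans exactly two
  compartments, one of them the cytosol (`_pc/_mc/_xc/_vc` naming).
  This is validated structurally, not assumed.
* **Biomass drains.** Each biomass component i has a drain
  `<name>_biomass` consuming c_i mmol of the component per unit biomass
  flux and producing a pool pseudo-species; the `Biomass` reaction
  consumes one unit of every pool. Drain flux therefore equals biomass
  flux, and the composition lives entirely in the drain coefficients.

Default bounds where a reaction states none: irreversible [0, 1000],
reversible [-1000, 1000]. Numerical tolerances: steady state and mass
balance 1e-9; a reported flux below 1e-8 counts as zero.

## Linear programming

FBA, pFBA, gap filling and every curation assay reduce to LPs solved
with HiGHS (scipy.optimize.linprog) behind a single interface. |v|
terms are linearized by the standard v = v+ - v- split. pFBA pins the
objective at its FBA optimum (exactly; one retry with 1e-9 slack covers
degenerate pinning) and minimizes total absolute flux. All distributions
that feed condition comparisons come from pFBA because plain FBA flux
vectors are degenerate and per-reaction fold changes would otherwise be
solver-dependent. The 50/50 nitrate/ammonium policy is an equality
coupling row (v_NO3 - v_NH4 = 0), not a pair of fixed values, so total
nitrogen floats with growth.

## Curation battery

* **Elemental balance** checks every biochemical and transport reaction
  against parsed formulas; exchanges, drains and the biomass reaction
  are boundary and exempt. Massless species (photons, electron-carrier
  proteins) carry an empty formula and are checked, not skipped.
* **Energy-generating cycles**: with every exchange closed, a
  dissipation reaction for ATP (hydrolysis), NADH or NADPH (oxidation)
  is added and maximized; any optimum above 1e-8 is a defect and the
  pFBA-active set is reported.
* **P/O ratios**: the donor-oxidizing step (complex I or succinate
  dehydrogenase) is pinned to 1, the reduced donor is regenerated by a
  pseudo-reaction pinned to the same flux, ATP is re-hydrolyzed by a
  pseudo-ATPase, photon and organic-carbon exchanges are closed and CO2
  is export-only (otherwise the free donor regeneration can power dark
  carbon fixation and inflate the ratio); mitochondrial ATP synthase
  flux is maximized. An uncoupling proton leak keeps the assay feasible
  when the synthase is blocked (the answer is then 0). On any
  proton-explicit chain the result equals (H+ translocated per donor) /
  (H+ consumed per ATP); the shipped stoichiometry (10 H+/NADH,
  6 H+/succinate, 16/3 H+/ATP) gives 1.875 and 1.125.
* **Gap filling** merges a weighted candidate pool and a demand for the
  target, minimizes the pool-weighted total |v| subject to production
  >= 1e-3 flux units, reports candidates with |v| > 1e-8, and verifies
  minimality by re-solving with each member removed (redundant members
  are pruned until the set is inclusion-minimal).
* **Yield checks** bound any product-per-substrate yield by the ratio
  of generalized degrees of reduction (C=4, H=1, O=-2, N=-3, P=5, S=6;
  nitrogen on the ammonia reference, matching plant N assimilation).
* **Biomass molecular weight**: coefficients are uniformly rescaled so
  that sum(c_i x MW_i) is exactly 1 g/mmol; components without formulas
  are rejected rather than guessed. The operation is idempotent.

## E-Flux

Gene activity is log2(mean FPKM + 1), mean over replicates first (the
log-then-mean alternative differs only in the third decimal at typical
replicate spreads). GPR trees evaluate with OR = sum and AND = min (the
original E-Flux convention); genes absent from a table score 0 with a
warning; an empty rule means "no constraint". Reaction scores are
normalized by the maximum over scored reactions within the condition,
so scores lie in [0, 1] and exactly one reaction (up to ties) attains
1. The normalized score scales the default bound magnitude (zero floor
for irreversible reactions); exchanges are reset to availability 1,
keeping a zero lower bound where the exchange was import-only. Measured
free amino acids (umol/gDW) replace the twenty amino-acid drain
coefficients (divided by 1000) and the composition is rescaled back to
1 g/mmol.

## The synthetic study

The generator emulates the inputs of a two-condition leaf study at desk
scale; it is first-class, tested code, and all of it is reproducible
bit-for-bit from one seed.

**Network.** ~90 enzymatic reactions across five compartments plus
transporters, 22 exchanges and 47 biomass drains (210 reactions total):
PSII/PSI with explicit thylakoid-lumen protons, linear electron flow to
NADPH and a ferredoxin-plastoquinone cyclic branch (ATP only), a lumped
Calvin cycle and photorespiratory arc through the peroxisome, cytosolic
glycolysis and sucrose metabolism (uptake lumped as 1 ATP per sucrose
for the H+-symport/PM-ATPase pair; invertase and sucrose-synthase
routes; a vacuolar invertase), full mitochondrial TCA with a weakly
expressed cytosolic PDH/CS/IDH bypass, the proton-explicit respiratory
chain above plus the external (non-pumping) NADH dehydrogenase, NR/NiR
nitrate reduction and plastidic GS/NADH-GOGAT fed by a malate shuttle,
and elementally balanced lumped biosynthesis of all 47 biomass
components (amino-acid nitrogen flows exclusively through
glutamate/glutamine, so all nitrogen assimilation crosses GS/GOGAT).
Two translocators are essential structure: the mitochondrial ANT and
the plastid envelope NTT — without the NTT the 1.29 ATP/NADPH
stoichiometry of linear electron flow leaves surplus plastidic ATP with
no sink and cyclic electron flow cannot operate. Every enzymatic
reaction carries a synthetic GPR (a seeded mixture of single genes,
ORs, ANDs and nested forms).

**Auto-balancing.** Each lumped reaction is closed exactly over a
triangular sequence of currency adjusters (SO4 for S, Pi for P, NH4 for
N, CO2 for C, H2O for O, H+ for H); construction fails loudly on any
residual, which is why the generated model passes the mass-balance
check by construction.

**Biomass.** 20 free amino acids (coefficients are the measured free
pools; there is no separate protein polymer, so the amino-acid block is
small and the carbohydrate/lipid/ion block carries most of the mass),
5 NTP/dNTP pools, starch/sucrose/cellulose, 4 lipid classes, 2
chlorophylls, 7 cofactors and 6 inorganic ions — 47 components rescaled
to exactly 1 g/mmol (~35 mmol C per gDW).

**Expression.** Per gene, the soil mean FPKM is drawn log-normally
around its pathway's median (sigma 0.05 — narrow, so condition contrasts
dominate gene-to-gene noise); the in-vitro mean applies the pathway
fold (photosynthesis/Calvin/TCA/glycolysis down, GS/GOGAT/sucrose and
the cytosolic TCA-bypass isoforms up, mirroring the observed
transcriptome directions); replicates add multiplicative log-normal
noise at CV 0.15.

**Amino-acid tables.** The five printed folds are exact; the remaining
15 acids share one closed-form fold making the total ratio exactly 2.0.
Because that identity caps the feasible glutamine share, the soil pool
is Gln 35 / Pro 30 / Asn 22 / Ser 20 / Val 18 umol/gDW (top five > 80%
of the pool) with 27.5 umol/gDW across the minor acids.

**Condition presets.** Soil: photons <= 15 per photosystem, no organic
carbon, CO2 exchange capacity 1 (the binding resource). In vitro:
photons <= 12, sucrose <= 0.01, CO2 capped at 0.55 — the poor gas
exchange of a closed vessel, and the mechanism that makes in-vitro
growth carbon-limited and slower. Both conditions pin a non-growth ATP
maintenance of 2.5 flux units; because the in-vitro biomass rate is
lower, maintenance and the sucrose-import ATP cost weigh more per unit
biomass, which (with cyclic electron flow as the marginal ATP source)
produces the higher per-biomass proton-pump ATP and lower per-biomass
NADPH of the in-vitro state. The TCA capacity (0.05) and the bypass
capacity (0.05, on weakly expressed genes) make the mitochondrial cycle
carry soil's 2-oxoglutarate and reducing-power demand while the
strongly induced cytosolic bypass takes over in vitro.

**What passing tests show — and do not.** The directional suite (lower
in-vitro growth, Calvin and TCA down, GS/GOGAT up, higher CEF share,
more ATP / less NADPH per biomass, sucrose used only in vitro, nitrogen
always 50/50) demonstrates that the workflow recovers the qualitative
physiology from transcriptome + metabolite + stoichiometric inputs
under controlled conditions. The synthetic network is far smaller than
a real genome-scale reconstruction, its expression model has no
batch structure or count noise, and fold-change magnitudes observed in
real leaf experiments depend on a full genome-scale reconstruction and
real data — only directions, never magnitudes, are asserted here.

## Design choices where the design was open

* Exchange sign convention is import-positive; presets read naturally
  ("photon input <= 12") at the cost of a sign flip against the common
  export-positive convention of other toolboxes (documented in the JSON
  dialect header).
* Localization-evidence ties within a tier: first record in file order
  wins, with a logged warning; evidence naming several compartments at
  the winning tier duplicates the reaction per compartment.
* The reported flux solver is pFBA everywhere (see above).
* Flux units are arbitrary but consistent (the study data anchor no
  absolute scale); all printed quantities are ratios, counts or
  per-biomass values.
* Problem sizes: the toy network (210 reactions) and vertex-enumeration
  or exhaustive-subset oracles on fixtures of <= 8 reactions / <= 12
  pool candidates keep the full test suite and the acceptance script in
  the seconds range.

## Known limitations

* No thermodynamic (Gibbs energy) constraints, kinetic/ODE modeling,
  FVA, loopless-FBA or flux sampling.
* SBML interchange is delegated to cobrapy; kind classification
  (exchange/drain/transport) on SBML read is inferred from the naming
  conventions, so models from other sources need those suffixes.
* The biomass "protein" is the free amino-acid pool by design of the
  measurement-incorporation step; a polymerized protein fraction would
  change absolute nitrogen fluxes (not the tested directions).
* Gap filling is LP-based (weighted flux, pruned to inclusion-minimal);
  it does not enumerate all alternate minimal sets.
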