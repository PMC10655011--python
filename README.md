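# phytoflux

Constraint-based modeling of compartmentalized plant leaf metabolism:
model assembly and curation, flux balance analysis (FBA/pFBA), E-Flux
transcriptome contextualization, and comparison of growth conditions —
exercised end-to-end on a synthetic five-compartment tobacco-style leaf
network.

## The problem

Plants grown *in vitro* (closed vessels, sucrose in the medium, limited
gas exchange) grow more slowly than soil-grown plants and rewire their
metabolism: photosynthesis and primary carbon metabolism are suppressed
while nitrogen assimilation through the GS/GOGAT cycle and free
amino-acid pools (glutamine above all) rise. Genome-scale metabolic
models make these shifts quantitative: with a stoichiometric matrix
`S`, flux balance analysis solves

```
max  c'v    s.t.   S v = 0,   v_min <= v <= v_max
```

with biomass maximization as the objective; parsimonious FBA (pFBA)
additionally minimizes total |v| at the optimum so per-reaction
comparisons are well defined. E-Flux turns replicate FPKM tables into
condition-specific bounds: gene scores `log2(mean FPKM + 1)` are
combined over gene–protein–reaction rules (OR = sum, AND = min),
normalized by the per-condition maximum, and scale each reaction's
default bound; exchanges are reset to availability magnitude 1
(import-positive).

The library implements the full workflow a curated plant model must
survive before its fluxes are trusted:

* **reconstruction** — draft assembly from reaction/GPR tables, a
  three-tier localization-evidence cascade (curated database >
  related-species model > predictor; cytosol default), cytosol-hub
  transporters (`_pc/_mc/_xc/_vc`), and a boundary of 22 exchange
  reactions (`_Cyto_tx`) plus 47 biomass drains (`_biomass`);
* **curation** — elemental balance, exclusion of energy-generating
  cycles (zero ATP/NADH/NADPH producible with all exchanges closed),
  P/O-ratio enforcement on a proton-explicit respiratory chain
  (1.875 ATP/NADH, 1.125 ATP/succinate), weighted-pFBA gap filling
  against a universal reaction pool, reduction-degree yield checks, and
  rescaling of the biomass equation to exactly 1 g/mmol;
* **simulation** — FBA/pFBA on HiGHS, CO2-constrained growth
  prediction with nitrogen coupled 50% nitrate / 50% ammonium, paired
  soil vs in-vitro simulation, per-reaction activity classes with
  log10 fold changes, pathway totals and gross ATP/NADH/NADPH
  accounting normalized by the biomass rate;
* **synthetic data** — a deterministic generator for the toy leaf model
  (photosystems with linear and cyclic electron flow, Calvin cycle,
  photorespiration, glycolysis, TCA plus a cytosolic bypass,
  proton-explicit oxidative phosphorylation, NR/NiR and GS/GOGAT,
  sucrose metabolism, 47 elementally balanced biosynthesis routes),
  replicate FPKM tables with configurable pathway fold changes, and
  free amino-acid tables reproducing measured fold changes (Gln 4.92x,
  Asn 1.92x, Ser 1.21x, Val 1.19x, Pro 0.82x, total 2x).

## Worked example

The numbered scripts under `analysis/` run the study end to end
(`--seed` controls every random draw):

```
python analysis/01_generate_inputs.py   --seed 1
python analysis/02_curate_model.py      --seed 1
python analysis/05_compare_conditions.py --seed 1
```

The curation step prints

```
PASS  po_ratio_NADH value=1.875 expected=1.875
PASS  po_ratio_succinate value=1.125 expected=1.125
PASS  biomass_molar_mass molar_mass=1.000000000000 g/mmol
```

and the paired condition comparison prints

```
biomass: soil 0.0257, in vitro 0.0180 (0.70x — slower in-vitro growth)
sucrose uptake: soil 0.0000, in vitro 0.0100
Calvin             soil   5.7998  in-vitro   3.3160  (down in vitro)
TCA                soil   0.0256  in-vitro   0.0215  (down in vitro)
GS                 soil   0.0076  in-vitro   0.0106  (UP in vitro)
GOGAT              soil   0.0057  in-vitro   0.0066  (UP in vitro)
CEF/LEF ratio: soil 0.223 -> in vitro 0.285 (cyclic electron flow share rises)
per-biomass proton-pump ATP: soil 213.8 -> in vitro 236.5; NADPH 78.7 -> 65.1
```

i.e. the in-vitro state grows more slowly on a mixed CO2 + sucrose
carbon supply, runs less Calvin cycle and TCA flux, assimilates more
nitrogen through GS/GOGAT, leans harder on cyclic electron flow, and
produces more proton-pump ATP but less NADPH per unit biomass. Pathway
totals are summed |flux| over the tagged member reactions (flux units
are arbitrary but consistent; biomass flux is gDW per unit time per
unit exchange capacity).

A `phytoflux` console script exposes the same functionality
(`phytoflux generate`, `phytoflux curate`, `phytoflux compare`).

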