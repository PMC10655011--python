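#!/usr/bin/env python
"""Generate every input of the study: the compartmentalized toy leaf
model (JSON + SBML + editable TSV tables), two-condition replicate FPKM
tables, free amino-acid tables and the pathway tag map.

Writes to results/inputs/.
"""

import argparse
import json
import os

from phytoflux import io
from phytoflux.synthetic import (
    GeneratorConfig,
    generate_amino_acid_tables,
    generate_expression_profiles,
    generate_toy_plant_model,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/inputs")
args = parser.parse_args()

os.makedirs(args.out, exist_ok=True)
config = GeneratorConfig(seed=args.seed)
model = generate_toy_plant_model(config)
io.write_model(model, os.path.join(args.out, "toy_plant.json"))
io.write_model(model, os.path.join(args.out, "toy_plant.xml"), format="sbml_fbc")
io.write_model(model, os.path.join(args.out, "tables"), format="tsv_tables")

expr_soil, expr_vitro = generate_expression_profiles(model, config)
expr_soil.to_tsv(os.path.join(args.out, "expression_soil.tsv"))
expr_vitro.to_tsv(os.path.join(args.out, "expression_in_vitro.tsv"))
aa_soil, aa_vitro = generate_amino_acid_tables(config)
aa_soil.to_csv(os.path.join(args.out, "amino_acids_soil.csv"))
aa_vitro.to_csv(os.path.join(args.out, "amino_acids_in_vitro.csv"))
with open(os.path.join(args.out, "pathway_tags.json"), "w") as fh:
    json.dump(model.pathway_tags, fh, indent=1)

exchanges = len(model.exchanges())
drains = len(model.biomass_drains())
print(f"model: {len(model.reactions)} reactions, {len(model.metabolites)} "
      f"metabolites, {sorted(model.compartments)} compartments")
print(f"boundary: {exchanges} exchange reactions (_Cyto_tx), "
      f"{drains} biomass drains (_biomass)")
print(f"expression: {len(expr_soil.rows)} genes x "
      f"{expr_soil.n_replicates} replicates x 2 conditions")
print(f"amino acids: soil total {aa_soil.total():.1f} umol/gDW, "
      f"in vitro {aa_vitro.total():.1f} (ratio "
      f"{aa_vitro.total() / aa_soil.total():.2f}, Gln fold "
      f"{aa_vitro.rows['Gln'] / aa_soil.rows['Gln']:.2f})")
print(f"outputs in {args.out}/")
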