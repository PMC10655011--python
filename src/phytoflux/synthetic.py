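"""Synthetic study inputs: toy plant model, FPKM tables, amino-acid tables.

The generated model is a deliberately small but biophysically structured
leaf cell with five compartments (cytosol, mitochondrion, plastid,
peroxisome, vacuole):

* photon inputs for PSII and PSI, linear electron flow to NADPH and a
  ferredoxin-plastoquinone cyclic branch that only builds proton motive
  force, with an explicit thylakoid-lumen proton pool;
* a lumped Calvin cycle (RuBisCO -> 3PG -> triose -> F6P/G6P -> RuBP
  regeneration) plus the RuBisCO oxygenase / photorespiratory salvage arc
  through the peroxisome;
* cytosolic glycolysis, sucrose uptake (one ATP per sucrose, lumping the
  H+-symporter and the plasma-membrane ATPase), invertase and sucrose
  synthase routes, and a vacuolar invertase;
* a full mitochondrial TCA cycle together with a weakly expressed
  cytosolic bypass (PDH/CS/IDH isoforms) that can supply 2-oxoglutarate
  without the mitochondrion;
* a proton-explicit respiratory chain translocating 10 H+ per NADH and
  6 H+ per succinate with an ATP synthase consuming 16/3 H+ per ATP, so
  the P/O ratios are exactly 1.875 and 1.125;
* nitrate reduction (cytosolic NR, plastidic NiR) and plastidic GS /
  NADH-GOGAT nitrogen assimilation fed by a malate shuttle;
* lumped, elementally balanced biosynthesis of every biomass component:
  20 amino acids (nitrogen strictly via glutamate/glutamine), NTP/dNTP
  pools, starch, sucrose, cellulose, four lipid classes, chlorophyll a/b,
  seven cofactors, and six inorganic ions - 47 drains in all, plus the
  22 exchanges of the boundary specification.

Every stoichiometry is closed exactly by an elemental auto-balancer over
currency species (SO4 -> Pi -> NH4 -> CO2 -> H2O -> H+), and the model is
constructed mass-balanced, energy-cycle-free and with a biomass molar
mass of exactly 1 g/mmol.  All randomness (GPR shapes, FPKM draws) is
driven by a single seed and outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curation import (
    BiomassComponent,
    BiomassComposition,
    apply_biomass_composition,
    rescale_biomass,
)
from .eflux import AMINO_ACIDS, AminoAcidTable, ExpressionTable
from .formulas import parse_formula
from .model import GPRExpr, MetabolicModel, Metabolite, Reaction

__all__ = [
    "GeneratorConfig",
    "generate_toy_plant_model",
    "default_biomass_composition",
    "generate_expression_profiles",
    "generate_amino_acid_tables",
    "AA_FOLDS",
]

# ---------------------------------------------------------------------------
# Species catalogue (formulas are charged-species conventions where redox
# matters; electron-carrier proteins are massless, their redox state is a
# distinct species)
# ---------------------------------------------------------------------------

SPECIES: dict[str, tuple[str, str | None]] = {
    # name, formula ("" = massless, None = unknown)
    "photon2": ("photon (PSII-absorbed)", ""),
    "photon1": ("photon (PSI-absorbed)", ""),
    "h": ("proton", "H"),
    "hlum": ("thylakoid lumen proton", "H"),
    "hims": ("mitochondrial intermembrane proton", "H"),
    "h2o": ("water", "H2O"),
    "o2": ("oxygen", "O2"),
    "co2": ("carbon dioxide", "CO2"),
    "h2o2": ("hydrogen peroxide", "H2O2"),
    "pi": ("orthophosphate", "HO4P"),
    "nh4": ("ammonium", "H4N"),
    "no3": ("nitrate", "NO3"),
    "no2": ("nitrite", "NO2"),
    "so4": ("sulfate", "O4S"),
    "k": ("potassium", "K"),
    "ca": ("calcium", "Ca"),
    "mg": ("magnesium", "Mg"),
    "fe": ("iron", "Fe"),
    "cl": ("chloride", "Cl"),
    "mn": ("manganese", "Mn"),
    "zn": ("zinc", "Zn"),
    "cu": ("copper", "Cu"),
    "mo": ("molybdenum", "Mo"),
    # energy and redox currencies
    "atp": ("ATP", "C10H12N5O13P3"),
    "adp": ("ADP", "C10H12N5O10P2"),
    "nad": ("NAD+", "C21H26N7O14P2"),
    "nadh": ("NADH", "C21H27N7O14P2"),
    "nadp": ("NADP+", "C21H25N7O17P3"),
    "nadph": ("NADPH", "C21H26N7O17P3"),
    # electron carriers
    "pq": ("plastoquinone", "C13H16O2"),
    "pqh2": ("plastoquinol", "C13H18O2"),
    "pcox": ("plastocyanin (oxidized)", ""),
    "pcred": ("plastocyanin (reduced)", ""),
    "fdox": ("ferredoxin (oxidized)", ""),
    "fdred": ("ferredoxin (reduced)", ""),
    "q": ("ubiquinone", "C14H18O4"),
    "qh2": ("ubiquinol", "C14H20O4"),
    "cytcox": ("cytochrome c (oxidized)", ""),
    "cytcred": ("cytochrome c (reduced)", ""),
    # central carbon
    "glc": ("glucose", "C6H12O6"),
    "fru": ("fructose", "C6H12O6"),
    "suc": ("sucrose", "C12H22O11"),
    "sucx": ("apoplastic sucrose", "C12H22O11"),
    "starch": ("starch (glucosyl unit)", "C6H10O5"),
    "cellulose": ("cellulose (glucosyl unit)", "C6H10O5"),
    "g6p": ("glucose 6-phosphate", "C6H11O9P"),
    "f6p": ("fructose 6-phosphate", "C6H11O9P"),
    "fdp": ("fructose 1,6-bisphosphate", "C6H10O12P2"),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P"),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P"),
    "dpg13": ("3-phospho-D-glyceroyl phosphate", "C3H4O10P2"),
    "pg3": ("3-phospho-glycerate", "C3H4O7P"),
    "pg2": ("2-phospho-glycerate", "C3H4O7P"),
    "pep": ("phosphoenolpyruvate", "C3H2O6P"),
    "pyr": ("pyruvate", "C3H3O3"),
    "rb15bp": ("ribulose 1,5-bisphosphate", "C5H8O11P2"),
    "pglyc": ("2-phosphoglycolate", "C2H2O6P"),
    "glyclt": ("glycolate", "C2H3O3"),
    "glx": ("glyoxylate", "C2H1O3"),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S"),
    "coa": ("coenzyme A", "C21H32N7O16P3S"),
    "cit": ("citrate", "C6H5O7"),
    "akg": ("2-oxoglutarate", "C5H4O5"),
    "succoa": ("succinyl-CoA", "C25H35N7O19P3S"),
    "succ": ("succinate", "C4H4O4"),
    "fum": ("fumarate", "C4H2O4"),
    "mal": ("malate", "C4H4O5"),
    "oaa": ("oxaloacetate", "C4H2O5"),
    # nucleotides and cofactors (biomass pools)
    "gtp": ("GTP", "C10H12N5O14P3"),
    "ctp": ("CTP", "C9H12N3O14P3"),
    "utp": ("UTP", "C9H11N2O15P3"),
    "datp": ("dATP (dNTP pool)", "C10H12N5O12P3"),
    "fad": ("FAD", "C27H33N9O15P2"),
    "thf": ("tetrahydrofolate", "C19H23N7O6"),
    "heme": ("heme b", "C34H32FeN4O4"),
    "asc": ("ascorbate", "C6H8O6"),
    # lipids and pigments
    "palm": ("palmitate", "C16H32O2"),
    "tag": ("triacylglycerol", "C51H98O6"),
    "pchol": ("phosphatidylcholine", "C40H80NO8P"),
    "mgdg": ("galactolipid MGDG", "C41H76O10"),
    "sqdg": ("sulfolipid SQDG", "C41H76O12S"),
    "chla": ("chlorophyll a", "C55H72MgN4O5"),
    "chlb": ("chlorophyll b", "C55H70MgN4O6"),
    # amino acids (neutral formulas; molecular weights for biomass)
    "ala": ("L-alanine", "C3H7NO2"),
    "arg": ("L-arginine", "C6H14N4O2"),
    "asn": ("L-asparagine", "C4H8N2O3"),
    "asp": ("L-aspartate", "C4H6NO4"),
    "cys": ("L-cysteine", "C3H7NO2S"),
    "gln": ("L-glutamine", "C5H10N2O3"),
    "glu": ("L-glutamate", "C5H8NO4"),
    "gly": ("glycine", "C2H5NO2"),
    "his": ("L-histidine", "C6H9N3O2"),
    "ile": ("L-isoleucine", "C6H13NO2"),
    "leu": ("L-leucine", "C6H13NO2"),
    "lys": ("L-lysine", "C6H14N2O2"),
    "met": ("L-methionine", "C5H11NO2S"),
    "phe": ("L-phenylalanine", "C9H11NO2"),
    "pro": ("L-proline", "C5H9NO2"),
    "ser": ("L-serine", "C3H7NO3"),
    "thr": ("L-threonine", "C4H9NO3"),
    "trp": ("L-tryptophan", "C11H12N2O2"),
    "tyr": ("L-tyrosine", "C9H11NO3"),
    "val": ("L-valine", "C5H11NO2"),
}

AA_SPECIES = {
    "Ala": "ala", "Arg": "arg", "Asn": "asn", "Asp": "asp", "Cys": "cys",
    "Gln": "gln", "Glu": "glu", "Gly": "gly", "His": "his", "Ile": "ile",
    "Leu": "leu", "Lys": "lys", "Met": "met", "Phe": "phe", "Pro": "pro",
    "Ser": "ser", "Thr": "thr", "Trp": "trp", "Tyr": "tyr", "Val": "val",
}

#: printed in-vitro/soil fold changes for the five dominant free amino
#: acids; the remaining 15 share a common fold solved so the total
#: concentration ratio is exactly 2.
AA_FOLDS = {"Gln": 4.92, "Asn": 1.92, "Ser": 1.21, "Val": 1.19, "Pro": 0.82}

#: default soil free amino-acid pool (umol per gDW); glutamine-dominated,
#: with the five most abundant acids carrying >80% of the total.
AA_SOIL_DEFAULT = {
    "Gln": 35.0, "Pro": 30.0, "Asn": 22.0, "Ser": 20.0, "Val": 18.0,
    "Glu": 6.0, "Asp": 3.0, "Ala": 3.0, "Gly": 2.0, "Thr": 2.0,
    "Ile": 1.5, "Leu": 1.5, "Lys": 1.5, "Arg": 1.5, "Phe": 1.5,
    "Tyr": 1.0, "His": 1.0, "Met": 0.8, "Cys": 0.7, "Trp": 0.5,
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, fixed by a single seed.

    The expression fold map gives the in-vitro/soil FPKM ratio per pathway
    tag (down for photosynthesis and primary carbon metabolism, up for
    nitrogen assimilation and sucrose use, mirroring the observed
    transcriptome directions); base FPKM medians set how strongly E-Flux
    bounds can bind per pathway.
    """

    seed: int = 1
    fpkm_noise_cv: float = 0.15
    n_replicates: int = 3
    expression_folds: dict[str, float] = field(default_factory=lambda: {
        "lef": 0.40, "cef": 2.5, "calvin": 0.30, "starch": 0.45,
        "photorespiration": 0.8, "glycolysis": 0.55, "tca": 0.12,
        "tca_bypass": 12.0, "oxphos": 0.45, "atp_synthase": 0.9,
        "gs": 4.0, "gogat": 3.0, "nitrate_reduction": 0.40,
        "sucrose": 3.0, "cell_wall": 0.5, "anaplerosis": 1.6,
        "amino_acid": 2.0, "nucleotide": 1.0, "cofactor": 1.0,
        "lipid": 0.6, "pigment": 0.5, "malate_shuttle": 1.8,
        "transport": 1.0, "other": 1.0,
    })
    base_fpkm_medians: dict[str, float] = field(default_factory=lambda: {
        "lef": 220.0, "cef": 25.0, "calvin": 320.0, "starch": 60.0,
        "photorespiration": 45.0, "glycolysis": 80.0, "tca": 40.0,
        "tca_bypass": 0.6, "oxphos": 60.0, "atp_synthase": 90.0,
        "gs": 50.0, "gogat": 35.0, "nitrate_reduction": 45.0,
        "sucrose": 20.0, "cell_wall": 70.0, "anaplerosis": 30.0,
        "maintenance": 30.0,
        "amino_acid": 25.0, "nucleotide": 20.0, "cofactor": 10.0,
        "lipid": 30.0, "pigment": 25.0, "malate_shuttle": 30.0,
        "transport": 40.0, "other": 30.0,
    })
    base_fpkm_sigma: float = 0.05  # lognormal sigma of base abundance
    #: per-condition exchange presets (flux units)
    photon_bounds: dict[str, float] = field(default_factory=lambda: {
        "soil": 15.0, "in_vitro": 12.0})
    sucrose_bounds: dict[str, float] = field(default_factory=lambda: {
        "soil": 0.0, "in_vitro": 0.01})
    co2_bounds: dict[str, float] = field(default_factory=lambda: {
        "soil": 1.0, "in_vitro": 0.55})
    maintenance_atp: float = 2.5
    aa_soil: dict[str, float] = field(default_factory=lambda: dict(AA_SOIL_DEFAULT))
    aa_folds: dict[str, float] = field(default_factory=lambda: dict(AA_FOLDS))
    aa_total_ratio: float = 2.0
    #: default bound magnitudes per pathway tag (flux units); pathways not
    #: listed get the generic enzymatic capacity
    capacity: dict[str, float] = field(default_factory=lambda: {
        "tca": 0.05, "tca_bypass": 0.05})
    generic_capacity: float = 100.0


# ---------------------------------------------------------------------------
# Model builder
# ---------------------------------------------------------------------------

_ADJUSTER_ORDER = ("so4", "pi", "nh4", "co2", "h2o", "h")
_ADJUSTER_ELEMENT = {"so4": "S", "pi": "P", "nh4": "N", "co2": "C",
                     "h2o": "O", "h": "H"}


class _Builder:
    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.model = MetabolicModel(name="toy_plant_leaf")
        self.rng = np.random.default_rng(config.seed)
        self._gene_counter = 0

    # -- species -----------------------------------------------------------
    def met(self, base: str, comp: str) -> str:
        mid = f"{base}_{comp}"
        if not self.model.has_metabolite(mid):
            name, formula = SPECIES[base]
            self.model.add_metabolite(Metabolite(
                id=mid, name=name, formula=formula, compartment=comp))
        return mid

    # -- auto-balancer -----------------------------------------------------
    def _balance(self, stoich: dict[str, float], comp: str,
                 adjusters: tuple[str, ...]) -> dict[str, float]:
        residual: dict[str, float] = {}
        for met_id, coeff in stoich.items():
            base = met_id.rsplit("_", 1)[0]
            formula = SPECIES[base][1]
            if formula is None:
                raise ValueError(f"species {base} has no formula")
            for el, n in parse_formula(formula).items():
                residual[el] = residual.get(el, 0.0) + coeff * n
        for adj in _ADJUSTER_ORDER:
            if adj not in adjusters:
                continue
            el = _ADJUSTER_ELEMENT[adj]
            need = residual.get(el, 0.0)
            if abs(need) < 1e-9:
                continue
            counts = parse_formula(SPECIES[adj][1])
            coeff = -need / counts[el]
            mid = self.met(adj, comp)
            stoich[mid] = stoich.get(mid, 0.0) + coeff
            for e2, n2 in counts.items():
                residual[e2] = residual.get(e2, 0.0) + coeff * n2
        bad = {el: v for el, v in residual.items() if abs(v) > 1e-9}
        if bad:
            raise ValueError(f"cannot balance reaction in {comp}: residual {bad}")
        return {k: v for k, v in stoich.items() if abs(v) > 1e-12}

    # -- GPRs --------------------------------------------------------------
    def _gpr(self, n_hint: int | None = None) -> GPRExpr:
        """Synthetic GPR: single gene, OR pair, AND pair or AND(OR, gene)."""
        shape = self.rng.integers(0, 4) if n_hint is None else n_hint

        def gene():
            self._gene_counter += 1
            return GPRExpr.leaf(f"NtS{self._gene_counter:04d}")

        if shape == 0:
            return gene()
        if shape == 1:
            return GPRExpr.or_(gene(), gene())
        if shape == 2:
            return GPRExpr.and_(gene(), gene())
        return GPRExpr.and_(GPRExpr.or_(gene(), gene()), gene())

    # -- reactions ---------------------------------------------------------
    def rxn(self, rid: str, comp: str, stoich: dict[str, float],
            tag: str, reversible: bool = False, kind: str = "biochemical",
            gpr: bool = True, balance: bool = True,
            adjusters: tuple[str, ...] = ("co2", "h2o", "h"),
            capacity: float | None = None, name: str = "") -> Reaction:
        full = {self.met(b, c): v
                for (b, c), v in ((k if isinstance(k, tuple) else (k, comp), v)
                                  for k, v in stoich.items())}
        if balance:
            full = self._balance(full, comp, adjusters)
        cap = capacity
        if cap is None:
            cap = self.config.capacity.get(tag, self.config.generic_capacity)
        reaction = Reaction(
            id=rid, stoichiometry=full,
            lower_bound=-cap if reversible else 0.0, upper_bound=cap,
            gpr=self._gpr() if gpr else None, kind=kind,
            subsystem=tag, name=name)
        self.model.add_reaction(reaction)
        self.model.pathway_tags[rid] = tag
        return reaction

    def transport(self, base: str, comp: str, reversible: bool = True,
                  tag: str = "transport", gpr: bool = False) -> Reaction:
        suffix = {"p": "pc", "m": "mc", "x": "xc", "v": "vc"}[comp]
        rid = f"{base.upper()}_{suffix}"
        return self.rxn(rid, comp,
                        {(base, comp): -1.0, (base, "c"): 1.0},
                        tag, reversible=reversible, kind="transport",
                        gpr=gpr, balance=False)

    def exchange(self, species: str, base: str, reversible: bool = False,
                 bound: float = 1000.0) -> Reaction:
        rid = f"{species}_Cyto_tx"
        reaction = Reaction(
            id=rid, stoichiometry={self.met(base, "c"): 1.0},
            lower_bound=-bound if reversible else 0.0, upper_bound=bound,
            kind="exchange", subsystem="exchange",
            name=f"{species} exchange (import-positive)")
        self.model.add_reaction(reaction)
        self.model.pathway_tags[rid] = "exchange"
        return reaction


#: the 22 boundary species: (exchange name, species base, reversible).
#: Energy sources, named mineral nutrients and the gas/water/proton
#: exchange; the micronutrient tail is a synthetic completion of the
#: named boundary species.
EXCHANGE_SPECIES: tuple[tuple[str, str, bool], ...] = (
    ("Glc", "glc", False), ("Sucrose", "sucx", False),
    ("Starch", "starch", False), ("Photon_PSII", "photon2", False),
    ("Photon_PSI", "photon1", False), ("NO3", "no3", False),
    ("NH4", "nh4", False), ("SO4", "so4", False), ("Pi", "pi", False),
    ("Ca", "ca", False), ("Fe", "fe", False), ("Mg", "mg", False),
    ("K", "k", False), ("CO2", "co2", True), ("O2", "o2", True),
    ("H2O", "h2o", True), ("H", "h", True), ("Cl", "cl", False),
    ("Mn", "mn", False), ("Zn", "zn", False), ("Cu", "cu", False),
    ("Mo", "mo", False),
)


def _add_boundary_exchanges(b: _Builder) -> None:
    for name, base, reversible in EXCHANGE_SPECIES:
        b.exchange(name, base, reversible=reversible)


def _add_light_reactions(b: _Builder) -> None:
    b.rxn("PSII_p", "p", {"photon2": -4, "h2o": -2, "pq": -2, "h": -4,
                          "o2": 1, "pqh2": 2, ("hlum", "p"): 4},
          "lef", name="photosystem II")
    b.rxn("Cytb6f_p", "p", {"pqh2": -2, "pcox": -4, "h": -4,
                            "pq": 2, "pcred": 4, ("hlum", "p"): 8},
          "lef", name="cytochrome b6f")
    b.rxn("PSI_p", "p", {"photon1": -4, "pcred": -4, "fdox": -4,
                         "pcox": 4, "fdred": 4}, "lef", name="photosystem I")
    b.rxn("FNR_p", "p", {"fdred": -4, "nadp": -2, "h": -2,
                         "fdox": 4, "nadph": 2}, "lef",
          name="ferredoxin-NADP+ reductase")
    b.rxn("CEF_p", "p", {"fdred": -4, "pq": -2, "h": -4,
                         "fdox": 4, "pqh2": 2}, "cef",
          name="ferredoxin-plastoquinone reductase (cyclic electron flow)")
    b.rxn("ATPSynth_p", "p", {("hlum", "p"): -14 / 3, "adp": -1, "pi": -1,
                              "atp": 1, "h2o": 1, "h": 11 / 3},
          "atp_synthase", name="chloroplast ATP synthase (14/3 H+ per ATP)")


def _add_calvin(b: _Builder) -> None:
    b.rxn("RBC_carb_p", "p", {"rb15bp": -1, "co2": -1, "h2o": -1,
                              "pg3": 2, "h": 2}, "calvin",
          name="RuBisCO carboxylase")
    b.rxn("PGK_p", "p", {"pg3": -1, "atp": -1, "dpg13": 1, "adp": 1}, "calvin")
    b.rxn("GAPDH_p", "p", {"dpg13": -1, "nadph": -1, "h": -1,
                           "g3p": 1, "nadp": 1, "pi": 1}, "calvin")
    b.rxn("CalvinRegen_p", "p", {"g3p": -5, "atp": -3, "h2o": -2,
                                 "rb15bp": 3, "adp": 3, "pi": 2, "h": 3},
          "calvin", name="RuBP regeneration (lumped)")
    b.rxn("TPI_p", "p", {"g3p": -1, "dhap": 1}, "calvin", reversible=True)
    b.rxn("FBA_p", "p", {"dhap": -1, "g3p": -1, "fdp": 1}, "calvin",
          reversible=True)
    b.rxn("FBP_p", "p", {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}, "calvin")
    b.rxn("PGI_p", "p", {"f6p": -1, "g6p": 1}, "calvin", reversible=True)
    b.rxn("StarchSynth_p", "p", {"g6p": -1, "atp": -1, "h2o": -1,
                                 "starch": 1, "adp": 1, "pi": 2, "h": 1},
          "starch", name="ADP-glucose starch synthesis (lumped)")
    # photorespiration arc
    b.rxn("RBC_oxy_p", "p", {"rb15bp": -1, "o2": -1, "pg3": 1, "pglyc": 1,
                             "h": 2}, "photorespiration",
          name="RuBisCO oxygenase")
    b.rxn("PGP_p", "p", {"pglyc": -1, "h2o": -1, "glyclt": 1, "pi": 1},
          "photorespiration")
    b.rxn("GOX_x", "x", {"glyclt": -1, "o2": -1, "glx": 1, "h2o2": 1},
          "photorespiration", name="glycolate oxidase")
    b.rxn("CAT_x", "x", {"h2o2": -2, "h2o": 2, "o2": 1}, "photorespiration",
          name="catalase")
    b.rxn("GGT_c", "c", {"glx": -1, "glu": -1, "gly": 1, "akg": 1},
          "photorespiration", name="glyoxylate aminotransferase")


def _add_glycolysis_sucrose(b: _Builder) -> None:
    b.rxn("HK_c", "c", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1},
          "glycolysis")
    b.rxn("PGI_c", "c", {"g6p": -1, "f6p": 1}, "glycolysis", reversible=True)
    b.rxn("PFK_c", "c", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1},
          "glycolysis")
    b.rxn("FBA_c", "c", {"fdp": -1, "dhap": 1, "g3p": 1}, "glycolysis",
          reversible=True)
    b.rxn("TPI_c", "c", {"dhap": -1, "g3p": 1}, "glycolysis", reversible=True)
    b.rxn("GAPDH_c", "c", {"g3p": -1, "nad": -1, "pi": -1,
                           "dpg13": 1, "nadh": 1, "h": 1},
          "glycolysis", reversible=True)
    b.rxn("PGK_c", "c", {"dpg13": -1, "adp": -1, "pg3": 1, "atp": 1},
          "glycolysis", reversible=True)
    b.rxn("PGM_c", "c", {"pg3": -1, "pg2": 1}, "glycolysis", reversible=True)
    b.rxn("ENO_c", "c", {"pg2": -1, "pep": 1, "h2o": 1}, "glycolysis",
          reversible=True)
    b.rxn("PYK_c", "c", {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1},
          "glycolysis")
    b.rxn("FRK_c", "c", {"fru": -1, "atp": -1, "f6p": 1, "adp": 1, "h": 1},
          "glycolysis", name="fructokinase")
    # sucrose metabolism
    b.rxn("SucUptake_c", "c", {"sucx": -1, "atp": -1, "h2o": -1,
                               "suc": 1, "adp": 1, "pi": 1, "h": 1},
          "sucrose", name="sucrose uptake (H+-symport + PM ATPase, 1 ATP)")
    b.rxn("INV_c", "c", {"suc": -1, "h2o": -1, "glc": 1, "fru": 1}, "sucrose",
          name="cytosolic invertase")
    b.rxn("SUS_c", "c", {"suc": -1, "pi": -1, "g6p": 1, "fru": 1}, "sucrose",
          name="sucrose synthase route (lumped with UGPase)")
    b.rxn("SPS_c", "c", {"g6p": -1, "f6p": -1, "h2o": -1, "suc": 1, "pi": 2},
          "sucrose", name="sucrose-phosphate synthase (lumped)")
    b.rxn("INV_v", "v", {"suc": -1, "h2o": -1, "glc": 1, "fru": 1}, "sucrose",
          name="vacuolar invertase")
    b.rxn("StarchDeg_c", "c", {"starch": -1, "h2o": -1, "glc": 1}, "sucrose",
          name="starch degradation (amylase, lumped)")
    b.rxn("Cellulose_c", "c", {"g6p": -1, "cellulose": 1, "pi": 1},
          "cell_wall", name="cellulose synthase (lumped)")
    # anaplerosis and the cytosolic malate shuttle
    b.rxn("PEPC_c", "c", {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1,
                          "h": 1}, "anaplerosis", name="PEP carboxylase")
    b.rxn("MDH_c", "c", {"oaa": -1, "nadh": -1, "h": -1, "mal": 1, "nad": 1},
          "malate_shuttle", reversible=True, name="cytosolic MDH")


def _add_tca_etc(b: _Builder) -> None:
    b.rxn("PDH_m", "m", {"pyr": -1, "coa": -1, "nad": -1,
                         "accoa": 1, "co2": 1, "nadh": 1}, "tca")
    b.rxn("CS_m", "m", {"accoa": -1, "oaa": -1, "h2o": -1,
                        "cit": 1, "coa": 1, "h": 1}, "tca")
    b.rxn("IDH_m", "m", {"cit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1},
          "tca", name="aconitase + isocitrate dehydrogenase (lumped)")
    b.rxn("AKGDH_m", "m", {"akg": -1, "coa": -1, "nad": -1,
                           "succoa": 1, "co2": 1, "nadh": 1}, "tca")
    b.rxn("SCS_m", "m", {"succoa": -1, "adp": -1, "pi": -1,
                         "succ": 1, "coa": 1, "atp": 1}, "tca")
    b.rxn("SDH_m", "m", {"succ": -1, "q": -1, "fum": 1, "qh2": 1}, "tca",
          name="succinate dehydrogenase (complex II)")
    b.rxn("FUM_m", "m", {"fum": -1, "h2o": -1, "mal": 1}, "tca",
          reversible=True)
    b.rxn("MDH_m", "m", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1},
          "tca", reversible=True)
    # weakly expressed cytosolic bypass isoforms (akg supply without the
    # mitochondrion; strongly induced in vitro)
    b.rxn("PDH_c", "c", {"pyr": -1, "coa": -1, "nad": -1,
                         "accoa": 1, "co2": 1, "nadh": 1}, "tca_bypass")
    b.rxn("CS_c", "c", {"accoa": -1, "oaa": -1, "h2o": -1,
                        "cit": 1, "coa": 1, "h": 1}, "tca_bypass")
    b.rxn("IDH_c", "c", {"cit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1},
          "tca_bypass")
    # proton-explicit respiratory chain: 10 H+ per NADH (4 + 4 + 2),
    # 6 H+ per succinate (via QH2: 4 + 2), ATP synthase 16/3 H+ per ATP
    b.rxn("NADH_DH_m", "m", {"nadh": -1, "q": -1, "h": -5,
                             "nad": 1, "qh2": 1, ("hims", "m"): 4},
          "oxphos", name="complex I (4 H+ pumped)")
    b.rxn("CytBC1_m", "m", {"qh2": -1, "cytcox": -2, "h": -2,
                            "q": 1, "cytcred": 2, ("hims", "m"): 4},
          "oxphos", name="complex III (4 H+ per QH2)")
    b.rxn("COX_m", "m", {"cytcred": -2, "o2": -0.5, "h": -4,
                         "cytcox": 2, "h2o": 1, ("hims", "m"): 2},
          "oxphos", name="complex IV (2 H+ pumped)")
    b.rxn("ATPSynth_m", "m", {("hims", "m"): -16 / 3, "adp": -1, "pi": -1,
                              "atp": 1, "h2o": 1, "h": 13 / 3},
          "atp_synthase", name="mitochondrial ATP synthase (16/3 H+ per ATP)")
    # external (non-pumping) NADH dehydrogenase oxidizing cytosolic NADH
    # into the ubiquinone pool - standard plant mitochondrial biochemistry
    b.rxn("NDext_m", "m", {("nadh", "c"): -1, ("h", "c"): -1, ("q", "m"): -1,
                           ("nad", "c"): 1, ("qh2", "m"): 1},
          "oxphos", kind="transport", balance=False,
          name="external NADH dehydrogenase (no H+ pumped)")


def _add_nitrogen(b: _Builder) -> None:
    b.rxn("NR_c", "c", {"no3": -1, "nadh": -1, "h": -1,
                        "no2": 1, "nad": 1, "h2o": 1}, "nitrate_reduction",
          name="nitrate reductase")
    b.rxn("NiR_p", "p", {"no2": -1, "fdred": -6, "h": -8,
                         "nh4": 1, "fdox": 6, "h2o": 2}, "nitrate_reduction",
          name="nitrite reductase (ferredoxin)")
    b.rxn("GS_p", "p", {"glu": -1, "nh4": -1, "atp": -1,
                        "gln": 1, "adp": 1, "pi": 1, "h": 1}, "gs",
          name="plastidic glutamine synthetase (GS2)")
    b.rxn("GOGAT_p", "p", {"gln": -1, "akg": -1, "nadh": -1, "h": -1,
                           "glu": 2, "nad": 1}, "gogat",
          name="NADH-GOGAT (glutamate synthase)")
    b.rxn("MDH_p", "p", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1},
          "malate_shuttle", reversible=True, name="plastidic MDH (NAD)")


def _add_amino_acids(b: _Builder) -> None:
    """Lumped amino-acid synthesis (cytosol).  Nitrogen enters exclusively
    through glutamate transamination or the glutamine amide group, so all
    nitrogen assimilation is forced through GS/GOGAT; NADH is the lumped
    reductant and the auto-balancer closes CO2/H2O/H+ (plus sulfate for
    Cys/Met and phosphate where phosphorylated intermediates appear)."""
    tag = "amino_acid"
    A = ("co2", "h2o", "h")
    AP = ("pi", "co2", "h2o", "h")
    AS = ("so4", "pi", "co2", "h2o", "h")
    b.rxn("AlaSyn_c", "c", {"pyr": -1, "glu": -1, "ala": 1, "akg": 1}, tag,
          adjusters=A)
    b.rxn("AspSyn_c", "c", {"oaa": -1, "glu": -1, "asp": 1, "akg": 1}, tag,
          adjusters=A)
    b.rxn("AsnSyn_c", "c", {"asp": -1, "gln": -1, "atp": -1,
                            "asn": 1, "glu": 1, "adp": 1, "pi": 1}, tag,
          adjusters=A)
    b.rxn("SerSyn_c", "c", {"pg3": -1, "glu": -1, "nad": -1,
                            "ser": 1, "akg": 1, "nadh": 1}, tag, adjusters=AP)
    b.rxn("GlySyn_c", "c", {"ser": -1, "gly": 1}, tag, adjusters=A)
    b.rxn("CysSyn_c", "c", {"ser": -1, "nadh": -4, "cys": 1, "nad": 4}, tag,
          adjusters=AS)
    b.rxn("ValSyn_c", "c", {"pyr": -2, "glu": -1, "nadh": -1,
                            "val": 1, "akg": 1, "nad": 1}, tag, adjusters=A)
    b.rxn("LeuSyn_c", "c", {"pyr": -3, "glu": -1, "nadh": -1,
                            "leu": 1, "akg": 1, "nad": 1}, tag, adjusters=A)
    b.rxn("IleSyn_c", "c", {"oaa": -1, "pyr": -1, "glu": -1, "nadh": -2,
                            "ile": 1, "akg": 1, "nad": 2}, tag, adjusters=A)
    b.rxn("ThrSyn_c", "c", {"oaa": -1, "glu": -1, "atp": -1, "nadh": -2,
                            "thr": 1, "akg": 1, "adp": 1, "pi": 1, "nad": 2},
          tag, adjusters=A)
    b.rxn("MetSyn_c", "c", {"oaa": -1, "glu": -1, "atp": -1, "nadh": -3,
                            "met": 1, "akg": 1, "adp": 1, "pi": 1, "nad": 3},
          tag, adjusters=AS)
    b.rxn("LysSyn_c", "c", {"oaa": -1, "pyr": -1, "glu": -2, "nadh": -2,
                            "lys": 1, "akg": 2, "nad": 2}, tag, adjusters=A)
    b.rxn("ProSyn_c", "c", {"glu": -1, "atp": -1, "nadh": -2,
                            "pro": 1, "adp": 1, "pi": 1, "nad": 2}, tag,
          adjusters=A)
    b.rxn("ArgSyn_c", "c", {"glu": -1, "gln": -1, "asp": -1, "atp": -3,
                            "arg": 1, "akg": 1, "adp": 3, "pi": 3}, tag,
          adjusters=A)
    b.rxn("HisSyn_c", "c", {"f6p": -1, "glu": -3, "atp": -2,
                            "his": 1, "akg": 3, "adp": 2, "pi": 2}, tag,
          adjusters=AP)
    b.rxn("PheSyn_c", "c", {"pep": -2, "g3p": -1, "glu": -1,
                            "phe": 1, "akg": 1}, tag, adjusters=AP)
    b.rxn("TyrSyn_c", "c", {"pep": -2, "g3p": -1, "glu": -1, "nad": -1,
                            "tyr": 1, "akg": 1, "nadh": 1}, tag, adjusters=AP)
    b.rxn("TrpSyn_c", "c", {"pep": -2, "g3p": -1, "gln": -1, "trp": 1}, tag,
          adjusters=AP)


def _add_biosynthesis(b: _Builder) -> None:
    # nucleotides: de novo purine/pyrimidine lumps (nitrogen from Gln/Asp/Gly)
    b.rxn("ATPdenovo_c", "c", {"f6p": -1, "gly": -1, "gln": -2, "asp": -2,
                               "atp": -5, "adp": 6, "glu": 2, "oaa": 2},
          "nucleotide", adjusters=("pi", "co2", "h2o", "h"),
          name="de novo purine synthesis to ATP (lumped)")
    b.rxn("GTPSyn_c", "c", {"atp": -1, "gtp": 1}, "nucleotide",
          adjusters=("h2o", "h"))
    b.rxn("UTPdenovo_c", "c", {"f6p": -1, "asp": -1, "gln": -1, "atp": -4,
                               "utp": 1, "adp": 4, "glu": 1},
          "nucleotide", adjusters=("pi", "co2", "h2o", "h"),
          name="de novo pyrimidine synthesis to UTP (lumped)")
    b.rxn("CTPSyn_c", "c", {"utp": -1, "gln": -1, "atp": -1,
                            "ctp": 1, "glu": 1, "adp": 1}, "nucleotide",
          adjusters=("pi", "h2o", "h"))
    b.rxn("dNTPSyn_c", "c", {"atp": -1, "nadh": -1, "h": -1,
                             "datp": 1, "nad": 1, "h2o": 1}, "nucleotide",
          name="ribonucleotide reduction (lumped dNTP pool)")
    # cofactors (7 biomass pools; tiny fluxes, nitrogen lumped from NH4)
    CF = ("nh4", "pi", "co2", "h2o", "h")
    b.rxn("NADSyn_c", "c", {"f6p": -2, "atp": -4, "nad": 1, "adp": 4},
          "cofactor", adjusters=CF)
    b.rxn("NADPSyn_c", "c", {"nad": -1, "atp": -1, "nadp": 1, "adp": 1},
          "cofactor", adjusters=("h2o", "h"), name="NAD kinase")
    b.rxn("FADSyn_c", "c", {"f6p": -2, "atp": -3, "fad": 1, "adp": 3},
          "cofactor", adjusters=CF)
    b.rxn("CoASyn_c", "c", {"asp": -1, "pyr": -2, "atp": -4, "nadh": -2,
                            "coa": 1, "adp": 4, "nad": 2}, "cofactor",
          adjusters=("nh4", "pi", "so4", "co2", "h2o", "h"))
    b.rxn("THFSyn_c", "c", {"f6p": -1, "glu": -1, "atp": -2,
                            "thf": 1, "adp": 2}, "cofactor", adjusters=CF)
    b.rxn("HemeSyn_c", "c", {"glu": -8, "fe": -1, "atp": -2,
                             "heme": 1, "adp": 2}, "cofactor", adjusters=CF,
          name="heme synthesis (ALA route, lumped)")
    b.rxn("AscSyn_c", "c", {"g6p": -1, "atp": -1, "asc": 1, "adp": 1},
          "cofactor", adjusters=("pi", "h2o", "h"))
    # lipids: plastidic fatty-acid synthesis, cytosolic assembly
    b.rxn("PDH_p", "p", {"pyr": -1, "coa": -1, "nad": -1,
                         "accoa": 1, "co2": 1, "nadh": 1}, "lipid",
          name="plastidic pyruvate dehydrogenase")
    b.rxn("FAS_p", "p", {"accoa": -8, "nadph": -14, "h": -14, "atp": -7,
                         "palm": 1, "coa": 8, "nadp": 14, "adp": 7},
          "lipid", adjusters=("pi", "co2", "h2o", "h"),
          name="fatty-acid synthesis to palmitate (lumped)")
    b.rxn("TAGSyn_c", "c", {"palm": -3, "dhap": -1, "nadh": -1, "atp": -1,
                            "tag": 1, "nad": 1, "adp": 1}, "lipid",
          adjusters=("pi", "co2", "h2o", "h"))
    b.rxn("PCSyn_c", "c", {"palm": -2, "dhap": -1, "atp": -2,
                           "pchol": 1, "adp": 2}, "lipid",
          adjusters=("nh4", "pi", "co2", "h2o", "h"))
    b.rxn("MGDGSyn_c", "c", {"palm": -2, "dhap": -1, "g6p": -1, "atp": -1,
                             "mgdg": 1, "adp": 1}, "lipid",
          adjusters=("pi", "co2", "h2o", "h"))
    b.rxn("SQDGSyn_c", "c", {"palm": -2, "dhap": -1, "g6p": -1, "atp": -1,
                             "sqdg": 1, "adp": 1}, "lipid",
          adjusters=("so4", "pi", "co2", "h2o", "h"))
    # chlorophylls (plastid; nitrogen from glutamate, the ALA route)
    b.rxn("ChlASyn_p", "p", {"glu": -4, "accoa": -17, "mg": -1, "atp": -6,
                             "nadph": -10, "h": -10, "chla": 1, "coa": 17,
                             "adp": 6, "nadp": 10}, "pigment",
          adjusters=("pi", "co2", "h2o", "h"),
          name="chlorophyll a synthesis (lumped)")
    b.rxn("ChlBSyn_p", "p", {"chla": -1, "h2o": -1, "chlb": 1, "h": 4},
          "pigment", name="chlorophyllide a oxygenase (lumped)")
    # growth-independent maintenance (pinned per condition)
    b.rxn("NGAM_c", "c", {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
          "maintenance", gpr=False, name="non-growth-associated maintenance")


def _add_transports(b: _Builder) -> None:
    for base in ("photon2", "photon1", "pg3", "dhap", "g6p", "pyr", "glu",
                 "gln", "akg", "mal", "oaa", "nh4", "no2", "co2", "o2",
                 "h2o", "pi", "h", "mg", "glyclt", "palm", "suc"):
        # sucrose enters the plastid nowhere; SUC_pc is not created
        if base == "suc":
            continue
        b.transport(base, "p")
    for base in ("pyr", "mal", "oaa", "akg", "co2", "o2", "h2o", "pi", "h"):
        b.transport(base, "m")
    # adenine nucleotide translocators: mitochondrial ANT exports ATP;
    # the plastid envelope NTT runs either way
    b.rxn("ANT_mc", "m", {("atp", "m"): -1, ("adp", "c"): -1,
                          ("atp", "c"): 1, ("adp", "m"): 1},
          "transport", kind="transport", gpr=False, balance=False)
    b.rxn("NTT_pc", "p", {("atp", "p"): -1, ("adp", "c"): -1,
                          ("atp", "c"): 1, ("adp", "p"): 1},
          "transport", kind="transport", gpr=False, balance=False)
    b.model.reaction("NTT_pc").lower_bound = -b.config.generic_capacity
    for base in ("glyclt", "glx", "o2", "h2o"):
        b.transport(base, "x")
    for base in ("suc", "glc", "fru", "h2o"):
        b.transport(base, "v")


def default_biomass_composition(config: GeneratorConfig | None = None,
                                ) -> BiomassComposition:
    """The 47-component biomass of the toy leaf, rescaled to 1 g/mmol.

    Amino-acid coefficients are the soil free pools (umol/gDW / 1000);
    the carbohydrate/lipid/pigment/cofactor/ion block is a synthetic
    stand-in for an unpublished full-model composition.
    """
    config = config or GeneratorConfig()
    entries: list[tuple[str, str, float]] = []
    for aa in AMINO_ACIDS:
        entries.append((aa, f"{AA_SPECIES[aa]}_c",
                        config.aa_soil[aa] / 1000.0))
    entries += [
        ("ATP", "atp_c", 0.002), ("GTP", "gtp_c", 0.0012),
        ("CTP", "ctp_c", 0.001), ("UTP", "utp_c", 0.001),
        ("dNTP", "datp_c", 0.0005),
        ("Starch", "starch_p", 1.2), ("Sucrose", "suc_c", 0.15),
        ("Cellulose", "cellulose_c", 2.8),
        ("TAG", "tag_c", 0.015), ("PhosphatidylCholine", "pchol_c", 0.02),
        ("MGDG", "mgdg_c", 0.025), ("SQDG", "sqdg_c", 0.01),
        ("ChlorophyllA", "chla_p", 0.006), ("ChlorophyllB", "chlb_p", 0.002),
        ("NAD", "nad_c", 0.002), ("NADP", "nadp_c", 0.001),
        ("FAD", "fad_c", 0.001), ("CoA", "coa_c", 0.001),
        ("THF", "thf_c", 0.0005), ("Heme", "heme_c", 0.0005),
        ("Ascorbate", "asc_c", 0.02),
        ("K", "k_c", 0.25), ("Ca", "ca_c", 0.08), ("Mg", "mg_c", 0.04),
        ("Cl", "cl_c", 0.15), ("Zn", "zn_c", 0.002), ("Mn", "mn_c", 0.002),
    ]
    components = [
        BiomassComponent(name, met_id, coeff, SPECIES[met_id.rsplit("_", 1)[0]][1])
        for name, met_id, coeff in entries
    ]
    assert len(components) == 47
    return rescale_biomass(BiomassComposition(components))


def _add_biomass(b: _Builder, composition: BiomassComposition) -> None:
    for comp in composition:
        pool = f"bm_{comp.name}_c"
        b.model.add_metabolite(Metabolite(
            id=pool, name=f"biomass pool: {comp.name}", formula=None,
            compartment="c"))
        drain = Reaction(
            id=f"{comp.name}_biomass",
            stoichiometry={comp.metabolite_id: -comp.coefficient, pool: 1.0},
            lower_bound=0.0, upper_bound=1000.0, kind="biomass_drain",
            subsystem="biomass", name=f"{comp.name} drain")
        b.model.add_reaction(drain)
        b.model.pathway_tags[drain.id] = "biomass"
    biomass = Reaction(
        id="Biomass",
        stoichiometry={f"bm_{comp.name}_c": -1.0 for comp in composition},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass",
        subsystem="biomass", name="biomass assembly (1 g/mmol)")
    b.model.add_reaction(biomass)
    b.model.pathway_tags["Biomass"] = "biomass"
    b.model.objective_reaction = "Biomass"


def generate_toy_plant_model(config: GeneratorConfig | None = None,
                             composition: BiomassComposition | None = None,
                             ) -> MetabolicModel:
    """Deterministically build the toy leaf model (see module docstring)."""
    config = config or GeneratorConfig()
    b = _Builder(config)
    _add_boundary_exchanges(b)
    _add_light_reactions(b)
    _add_calvin(b)
    _add_glycolysis_sucrose(b)
    _add_tca_etc(b)
    _add_nitrogen(b)
    _add_amino_acids(b)
    _add_biosynthesis(b)
    _add_transports(b)
    composition = composition or default_biomass_composition(config)
    _add_biomass(b, composition)
    b.model.validate()
    return b.model


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------

def generate_expression_profiles(model: MetabolicModel,
                                 config: GeneratorConfig | None = None,
                                 ) -> tuple[ExpressionTable, ExpressionTable]:
    """Two-condition, replicate FPKM tables for every gene in the model.

    Per gene: soil mean drawn log-normally around its pathway's median
    FPKM; in-vitro mean = soil mean x the pathway's fold change;
    replicates apply multiplicative log-normal noise at the configured CV.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1)
    folds = config.expression_folds
    medians = config.base_fpkm_medians
    for tag in set(model.pathway_tags.values()):
        if tag in ("exchange", "biomass", "maintenance"):
            continue
        if tag not in folds:
            raise KeyError(f"pathway tag {tag!r} missing from the fold map")

    sigma_noise = math.sqrt(math.log(1.0 + config.fpkm_noise_cv ** 2))
    soil_rows: dict[str, tuple[float, ...]] = {}
    vitro_rows: dict[str, tuple[float, ...]] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        tag = model.pathway_tags.get(rxn.id, "other")
        median = medians.get(tag, medians["other"])
        fold = folds.get(tag, 1.0)
        for gene in sorted(rxn.gpr.genes()):
            if gene in soil_rows:
                continue
            base = median * rng.lognormal(0.0, config.base_fpkm_sigma)
            means = {"soil": base, "vitro": base * fold}
            noise = rng.lognormal(0.0, sigma_noise,
                                  size=(2, config.n_replicates)) \
                if config.fpkm_noise_cv > 0 else np.ones((2, config.n_replicates))
            soil_rows[gene] = tuple(means["soil"] * noise[0])
            vitro_rows[gene] = tuple(means["vitro"] * noise[1])
    return (ExpressionTable("soil", soil_rows),
            ExpressionTable("in_vitro", vitro_rows))


# ---------------------------------------------------------------------------
# Amino-acid tables
# ---------------------------------------------------------------------------

def generate_amino_acid_tables(config: GeneratorConfig | None = None,
                               ) -> tuple[AminoAcidTable, AminoAcidTable]:
    """Soil and in-vitro free amino-acid tables.

    The five printed fold changes are applied exactly; the remaining 15
    acids share a common fold solved in closed form so the total
    concentration ratio equals the configured value (2.0 by default).
    """
    config = config or GeneratorConfig()
    soil = dict(config.aa_soil)
    total = sum(soil.values())
    fixed = config.aa_folds
    fixed_total = sum(soil[aa] * f for aa, f in fixed.items())
    rest_total = total - sum(soil[aa] for aa in fixed)
    if rest_total <= 0:
        raise ValueError("soil table leaves no mass for the unprinted acids")
    common = (config.aa_total_ratio * total - fixed_total) / rest_total
    if common <= 0:
        raise ValueError(
            "printed folds already exceed the target total ratio; "
            "common fold would be non-positive")
    vitro = {aa: conc * fixed.get(aa, common) for aa, conc in soil.items()}
    return (AminoAcidTable("soil", soil), AminoAcidTable("in_vitro", vitro))


def default_boundary_spec(config: GeneratorConfig | None = None):
    """The shipped boundary specification: the 22 exchanges and the
    47-component biomass of the toy leaf (coefficients in mmol/gDW after
    rescaling to 1 g/mmol)."""
    from .reconstruction import BoundarySpec

    composition = default_biomass_composition(config)
    return BoundarySpec(
        exchanges=[(name, "both" if reversible else "import", 1000.0)
                   for name, _, reversible in EXCHANGE_SPECIES],
        biomass_components=[(c.metabolite_id, c.coefficient)
                            for c in composition])


def generate_condition_specs(model: MetabolicModel,
                             config: GeneratorConfig | None = None):
    """Convenience: the soil and in-vitro ConditionSpecs with their
    generated expression and amino-acid tables attached."""
    from .conditions import ConditionSpec

    config = config or GeneratorConfig()
    expr_soil, expr_vitro = generate_expression_profiles(model, config)
    aa_soil, aa_vitro = generate_amino_acid_tables(config)
    tables = {"soil": (expr_soil, aa_soil), "in_vitro": (expr_vitro, aa_vitro)}
    specs = []
    for name in ("soil", "in_vitro"):
        expr, aa = tables[name]
        specs.append(ConditionSpec(
            name=name,
            photon_bound=config.photon_bounds[name],
            sucrose_bound=config.sucrose_bounds[name],
            co2_bound=config.co2_bounds[name],
            maintenance_atp=config.maintenance_atp,
            expression_table=expr,
            amino_acid_table=aa))
    return tuple(specs)
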