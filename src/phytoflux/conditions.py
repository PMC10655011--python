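"""Condition presets, paired simulation and flux/energy comparison.

A condition couples an expression table and an amino-acid table to an
exchange preset: photons open to a ceiling, sucrose availability (zero
for soil-grown leaves, the medium supply in vitro), CO2 exchange capped
(closed culture vessels exchange gas poorly), all other organic carbon
closed, nitrogen uptake coupled 50% nitrate / 50% ammonium, and a pinned
non-growth ATP maintenance.  Simulation is E-Flux contextualization,
amino-acid biomass update, preset application, then pFBA with biomass
maximization (pFBA so that per-reaction comparisons are well defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .curation import BiomassComposition, apply_biomass_composition
from .eflux import AminoAcidTable, ExpressionTable, apply_eflux, incorporate_amino_acids
from .fba import FluxSolution, fifty_fifty_nitrogen, solve_pfba
from .model import MetabolicModel, ZERO_FLUX_TOL

__all__ = [
    "ConditionSpec",
    "simulate_condition",
    "FluxComparison",
    "compare_fluxes",
    "account_energy_redox",
    "summarize_pathways",
]


@dataclass
class ConditionSpec:
    name: str  # soil | in_vitro | custom
    photon_bound: float
    sucrose_bound: float
    co2_bound: float = 1.0
    maintenance_atp: float = 0.0
    nitrogen_coupling: str = "fifty_fifty"
    expression_table: ExpressionTable | None = None
    amino_acid_table: AminoAcidTable | None = None

    def __post_init__(self):
        if self.name == "soil" and self.sucrose_bound != 0:
            raise ValueError("the soil preset has no sucrose supply")
        for label, value in (("photon", self.photon_bound),
                             ("sucrose", self.sucrose_bound),
                             ("co2", self.co2_bound)):
            if value < 0:
                raise ValueError(f"{label} bound must be >= 0")


@dataclass
class ConditionResult:
    spec: ConditionSpec
    solution: FluxSolution
    context_model: MetabolicModel
    composition: BiomassComposition


def simulate_condition(model: MetabolicModel,
                       composition: BiomassComposition,
                       spec: ConditionSpec) -> ConditionResult:
    """Contextualize and solve one condition (see module docstring)."""
    if spec.expression_table is None:
        raise ValueError(f"condition {spec.name}: no expression table")
    context = apply_eflux(model, spec.expression_table).model
    comp = composition
    if spec.amino_acid_table is not None:
        comp = incorporate_amino_acids(composition, spec.amino_acid_table)
    apply_biomass_composition(context, comp)

    for rxn in context.reactions:
        if rxn.kind != "exchange":
            continue
        if rxn.id in ("Photon_PSII_Cyto_tx", "Photon_PSI_Cyto_tx"):
            rxn.lower_bound, rxn.upper_bound = 0.0, spec.photon_bound
        elif rxn.id == "Sucrose_Cyto_tx":
            rxn.lower_bound, rxn.upper_bound = 0.0, spec.sucrose_bound
        elif rxn.id in ("Glc_Cyto_tx", "Starch_Cyto_tx"):
            rxn.lower_bound, rxn.upper_bound = 0.0, 0.0
        elif rxn.id == "CO2_Cyto_tx":
            rxn.lower_bound, rxn.upper_bound = -1.0, spec.co2_bound
    pins = {}
    if context.has_reaction("NGAM_c") and spec.maintenance_atp > 0:
        ngam = context.reaction("NGAM_c")
        ngam.lower_bound, ngam.upper_bound = 0.0, 1000.0
        pins["NGAM_c"] = spec.maintenance_atp
    couplings = []
    if spec.nitrogen_coupling == "fifty_fifty":
        couplings.append(fifty_fifty_nitrogen(context))

    solution = solve_pfba(context, context.objective_reaction, pins=pins,
                          couplings=couplings)
    if not solution.optimal:
        binding = [r.id for r in context.reactions
                   if r.upper_bound == 0.0 and r.kind == "exchange"]
        raise RuntimeError(
            f"condition {spec.name} is {solution.status}; "
            f"closed exchanges: {binding}")
    return ConditionResult(spec, solution, context, comp)


# ---------------------------------------------------------------------------
# Flux comparison (the in-vitro/soil fold-change view)
# ---------------------------------------------------------------------------

@dataclass
class FluxComparison:
    reaction_id: str
    flux_soil: float
    flux_vitro: float
    cls: str  # both | vitro_only | soil_only | neither
    log10_fc: float | None  # defined only for cls == "both"


def compare_fluxes(sol_soil: FluxSolution, sol_vitro: FluxSolution,
                   tol: float = ZERO_FLUX_TOL) -> list[FluxComparison]:
    """Classify reactions by which condition carries flux; for reactions
    active in both, report log10(|v_vitro| / |v_soil|)."""
    if set(sol_soil.fluxes) != set(sol_vitro.fluxes):
        raise ValueError("solutions cover different reaction sets")
    out = []
    for rid in sol_soil.fluxes:
        vs, vv = sol_soil.fluxes[rid], sol_vitro.fluxes[rid]
        active_s, active_v = abs(vs) > tol, abs(vv) > tol
        if active_s and active_v:
            cls, fc = "both", math.log10(abs(vv) / abs(vs))
        elif active_v:
            cls, fc = "vitro_only", None
        elif active_s:
            cls, fc = "soil_only", None
        else:
            cls, fc = "neither", None
        out.append(FluxComparison(rid, vs, vv, cls, fc))
    return out


# ---------------------------------------------------------------------------
# Energy / redox accounting
# ---------------------------------------------------------------------------

def _stoich_of(rxn, prefix: str) -> float:
    return sum(coeff for met, coeff in rxn.stoichiometry.items()
               if met.rsplit("_", 1)[0] == prefix)


def account_energy_redox(model: MetabolicModel, sol: FluxSolution,
                         biomass_flux: float) -> dict:
    """Gross energy/redox production of a flux state.

    ATP_protonpump sums ATP made by the proton-pumping ATP synthases
    (reactions tagged atp_synthase) weighted by their ATP stoichiometry;
    NADH_net / NADPH_net sum gross positive production over all reactions
    (net turnover is zero at steady state, so gross production is the
    meaningful magnitude).  Values are reported raw and per unit biomass.
    """
    atp_pump = 0.0
    for rid, tag in model.pathway_tags.items():
        if tag == "atp_synthase":
            v = sol.fluxes.get(rid, 0.0)
            atp_pump += v * _stoich_of(model.reaction(rid), "atp")
    nadh = nadph = 0.0
    for rxn in model.reactions:
        v = sol.fluxes.get(rxn.id, 0.0)
        if abs(v) <= ZERO_FLUX_TOL:
            continue
        made_nadh = v * _stoich_of(rxn, "nadh")
        made_nadph = v * _stoich_of(rxn, "nadph")
        if made_nadh > 0:
            nadh += made_nadh
        if made_nadph > 0:
            nadph += made_nadph
    result = {"ATP_protonpump": atp_pump, "NADH_net": nadh, "NADPH_net": nadph}
    if biomass_flux > ZERO_FLUX_TOL:
        result["per_biomass"] = {k: v / biomass_flux for k, v in result.items()}
    else:
        result["per_biomass"] = None
        result["warning"] = "biomass flux <= 0; normalized values undefined"
    return result


# ---------------------------------------------------------------------------
# Pathway summaries
# ---------------------------------------------------------------------------

#: summary keys -> pathway tags of the shipped toy model
DEFAULT_PATHWAYS = {
    "LEF": "lef", "CEF": "cef", "Calvin": "calvin",
    "glycolysis": "glycolysis", "TCA": "tca", "TCA_bypass": "tca_bypass",
    "GS": "gs", "GOGAT": "gogat", "nitrate_reduction": "nitrate_reduction",
    "sucrose_uptake": "sucrose",
}


def summarize_pathways(model: MetabolicModel, sol: FluxSolution,
                       pathways: dict[str, str] | None = None) -> dict:
    """Total |flux| per pathway plus the CEF/LEF and GS/GOGAT ratios."""
    pathways = pathways or DEFAULT_PATHWAYS
    known = set(model.pathway_tags.values())
    totals: dict[str, float] = {}
    for label, tag in pathways.items():
        if tag not in known:
            raise KeyError(f"unknown pathway tag {tag!r}")
        totals[label] = sum(abs(sol.fluxes.get(rid, 0.0))
                            for rid, t in model.pathway_tags.items() if t == tag)
    summary = dict(totals)
    if "CEF" in totals and "LEF" in totals:
        summary["CEF_over_LEF"] = (totals["CEF"] / totals["LEF"]
                                   if totals["LEF"] > ZERO_FLUX_TOL else None)
    if "GS" in totals and "GOGAT" in totals:
        summary["GS_over_GOGAT"] = (totals["GS"] / totals["GOGAT"]
                                    if totals["GOGAT"] > ZERO_FLUX_TOL else None)
    return summary
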