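"""Model curation battery.

The checks and repairs a compartmentalized plant model must pass before its
flux predictions are trusted:

* directionality/reversibility revision from a rule table;
* exclusion of energy-generating cycles (no ATP/NADH/NADPH can be produced
  with every exchange closed);
* P/O ratio enforcement on the proton-explicit respiratory chain
  (ATP per NADH 1.875 and per succinate 1.125 with the shipped
  10 / 6 H+ translocated per donor and 16/3 H+ per ATP stoichiometry);
* weighted-pFBA gap filling against a universal reaction pool;
* theoretical-maximum-yield checks from degrees of reduction;
* biomass molecular-weight correction so the biomass pseudo-species weighs
  exactly 1 g/mmol.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace

from .fba import solve_fba, solve_pfba, solve_problem, FluxProblem
from .formulas import degree_of_reduction, molecular_weight
from .model import (
    DEFAULT_UPPER,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ZERO_FLUX_TOL,
)

__all__ = [
    "ReversibilityRule",
    "apply_reversibility_rules",
    "EnergyCycleReport",
    "detect_energy_cycles",
    "compute_po_ratio",
    "UniversalPool",
    "GapfillError",
    "gapfill_weighted_pfba",
    "YieldCheck",
    "check_max_yield",
    "BiomassComponent",
    "BiomassComposition",
    "rescale_biomass",
    "run_curation_battery",
]


# ---------------------------------------------------------------------------
# Reversibility rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversibilityRule:
    """Directionality assignment for reactions matching an id pattern."""

    pattern: str  # exact reaction id or fnmatch glob
    directionality: str  # forward | reverse | reversible

    def __post_init__(self):
        if self.directionality not in ("forward", "reverse", "reversible"):
            raise ValueError(f"unknown directionality {self.directionality!r}")


def apply_reversibility_rules(model: MetabolicModel,
                              rules: list[ReversibilityRule],
                              ) -> list[str]:
    """Apply rules in order; later rules win.  Bounds are only narrowed or
    mirrored, never widened beyond the default magnitude.  Returns the ids
    of reactions whose bounds changed."""
    changed = []
    for rxn in model.reactions:
        if rxn.kind in ("exchange", "biomass_drain", "biomass"):
            continue
        for rule in rules:
            if not fnmatch.fnmatchcase(rxn.id, rule.pattern):
                continue
            lb, ub = rxn.lower_bound, rxn.upper_bound
            if rule.directionality == "forward":
                new = (max(lb, 0.0), ub)
            elif rule.directionality == "reverse":
                new = (lb, min(ub, 0.0))
            else:  # reversible: mirror the forward capacity, capped at default
                mag = min(max(abs(lb), abs(ub)), DEFAULT_UPPER)
                new = (-mag, mag)
            if new != (lb, ub):
                rxn.lower_bound, rxn.upper_bound = new
                if rxn.id not in changed:
                    changed.append(rxn.id)
    return changed


# ---------------------------------------------------------------------------
# Energy-generating cycle detection
# ---------------------------------------------------------------------------

#: currency -> (dissipation stoichiometry over base species names)
_DISSIPATION = {
    "ATP": {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
    "NADH": {"nadh": -1, "nad": 1, "h": 1},
    "NADPH": {"nadph": -1, "nadp": 1, "h": 1},
}


@dataclass
class EnergyCycleReport:
    currency: str
    compartment: str
    max_production: float
    participating_reactions: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return self.max_production <= ZERO_FLUX_TOL


def _find_currency_compartment(model: MetabolicModel, species: list[str],
                               ) -> str | None:
    for comp in ("c", "p", "m", "x", "v"):
        if all(model.has_metabolite(f"{s}_{comp}") for s in species):
            return comp
    return None


def detect_energy_cycles(model: MetabolicModel, currency: str,
                         ) -> EnergyCycleReport:
    """Maximum closed-system production of an energy currency.

    Every exchange bound is set to 0, a dissipation reaction for the
    currency is added (e.g. ATP + H2O -> ADP + Pi + H) and its flux
    maximized.  A curated model returns 0; a positive optimum means an
    energy-generating cycle, and the minimal active reaction set from the
    pFBA solution is reported.
    """
    if currency not in _DISSIPATION:
        raise ValueError(f"unknown currency {currency!r} (ATP, NADH or NADPH)")
    stoich = _DISSIPATION[currency]
    comp = _find_currency_compartment(model, list(stoich))
    if comp is None:
        raise ModelValidationError(
            f"currency species for {currency} absent from every compartment")

    probe = model.copy()
    diss_id = f"__dissipate_{currency}"
    probe.add_reaction(Reaction(
        id=diss_id,
        stoichiometry={f"{s}_{comp}": float(v) for s, v in stoich.items()},
        lower_bound=0.0, upper_bound=DEFAULT_UPPER))
    overrides = {r.id: (0.0, 0.0) for r in probe.exchanges()}
    sol = solve_fba(probe, diss_id, sense="max", bound_overrides=overrides)
    if not sol.optimal:
        return EnergyCycleReport(currency, comp, 0.0)
    production = sol.objective_value
    participants: list[str] = []
    if production > ZERO_FLUX_TOL:
        psol = solve_pfba(probe, diss_id, sense="max", bound_overrides=overrides)
        participants = sorted(
            rid for rid, v in psol.fluxes.items()
            if abs(v) > ZERO_FLUX_TOL and rid != diss_id)
    return EnergyCycleReport(currency, comp, float(production), participants)


# ---------------------------------------------------------------------------
# P/O ratio
# ---------------------------------------------------------------------------

def compute_po_ratio(model: MetabolicModel, donor: str = "NADH",
                     donor_reaction: str | None = None,
                     synthase_reaction: str = "ATPSynth_m",
                     ) -> float:
    """ATP synthesized per electron donor oxidized by the mitochondrial
    respiratory chain.

    The assay closes every energy-bearing exchange (photons and organic
    carbon), pins the donor-oxidizing reaction (complex I for NADH,
    succinate dehydrogenase for succinate) to flux 1, regenerates the
    reduced donor and hydrolyzes the ATP made through massless assay
    reactions, and maximizes mitochondrial ATP synthase flux by FBA.

    On a proton-explicit chain the result equals
    (H+ translocated per donor) / (H+ consumed per ATP).
    """
    defaults = {"NADH": "NADH_DH_m", "succinate": "SDH_m"}
    if donor_reaction is None:
        if donor not in defaults:
            raise ValueError(f"unknown donor {donor!r} (NADH or succinate)")
        donor_reaction = defaults[donor]
    for rid in (donor_reaction, synthase_reaction):
        if not model.has_reaction(rid):
            raise ModelValidationError(f"respiratory reaction {rid} not in model")

    probe = model.copy()

    def need(met_id):
        if not probe.has_metabolite(met_id):
            raise ModelValidationError(
                f"P/O assay requires metabolite {met_id} (blocked ETC step)")
        return met_id

    if donor == "NADH":
        regen = {need("nad_m"): -1.0, need("h_m"): -1.0, need("nadh_m"): 1.0}
    else:
        regen = {need("fum_m"): -1.0, need("h_m"): -2.0, need("succ_m"): 1.0}
    probe.add_reaction(Reaction("__regen_donor", regen, 0.0, DEFAULT_UPPER))
    probe.add_reaction(Reaction(
        "__atp_sink",
        {need("atp_m"): -1.0, need("h2o_m"): -1.0, need("adp_m"): 1.0,
         need("pi_m"): 1.0, need("h_m"): 1.0},
        0.0, DEFAULT_UPPER))
    # inner-membrane proton leak: keeps the assay feasible when the
    # synthase is blocked, and is never used at the optimum
    probe.add_reaction(Reaction(
        "__h_leak", {need("hims_m"): -1.0, need("h_m"): 1.0},
        0.0, DEFAULT_UPPER))

    # the assay may drive the donor step harder than its in-vivo capacity
    overrides: dict[str, tuple[float, float]] = {
        donor_reaction: (0.0, DEFAULT_UPPER)}
    closed = ("Photon_PSII_Cyto_tx", "Photon_PSI_Cyto_tx", "Sucrose_Cyto_tx",
              "Glc_Cyto_tx", "Starch_Cyto_tx")
    for r in probe.exchanges():
        if r.id in closed:
            overrides[r.id] = (0.0, 0.0)
        elif r.id == "CO2_Cyto_tx":
            # export only: the free donor regeneration must not power dark
            # carbon fixation feeding extra electrons into the chain
            overrides[r.id] = (min(r.lower_bound, 0.0), 0.0)
    # the regeneration pseudo-flux is pinned to the donor flux so the
    # assay injects exactly one reduced donor per donor oxidized
    sol = solve_fba(probe, synthase_reaction, sense="max",
                    pins={donor_reaction: 1.0, "__regen_donor": 1.0},
                    bound_overrides=overrides)
    if not sol.optimal:
        raise ModelValidationError(
            f"P/O assay infeasible: cannot sustain unit flux through "
            f"{donor_reaction} (status {sol.status})")
    return float(sol.objective_value)


# ---------------------------------------------------------------------------
# Weighted-pFBA gap filling
# ---------------------------------------------------------------------------

@dataclass
class UniversalPool:
    """Candidate reactions (e.g. drawn from a reaction database) with
    positive per-reaction weights for parsimonious gap filling."""

    reactions: list[Reaction]
    weights: dict[str, float]
    metabolites: list[Metabolite] = field(default_factory=list)

    def __post_init__(self):
        for r in self.reactions:
            w = self.weights.get(r.id)
            if w is None or w <= 0:
                raise ValueError(f"pool reaction {r.id} needs a positive weight")


class GapfillError(RuntimeError):
    def __init__(self, message: str, dead_end_precursors: list[str] | None = None):
        super().__init__(message)
        self.dead_end_precursors = dead_end_precursors or []


def _merged_with_pool(model: MetabolicModel, pool: UniversalPool,
                      target: str) -> tuple[MetabolicModel, str]:
    merged = model.copy()
    for met in pool.metabolites:
        if not merged.has_metabolite(met.id):
            merged.add_metabolite(met)
    for rxn in pool.reactions:
        if merged.has_reaction(rxn.id):
            raise ValueError(f"pool id {rxn.id} collides with a model reaction")
        merged.add_reaction(replace(rxn, stoichiometry=dict(rxn.stoichiometry)))
    demand = f"__demand_{target}"
    merged.add_reaction(Reaction(demand, {target: -1.0}, 0.0, DEFAULT_UPPER))
    return merged, demand


def _dead_end_precursors(model: MetabolicModel, target: str) -> list[str]:
    """Metabolites backward-reachable from the target that nothing produces."""
    producers: dict[str, list[Reaction]] = {m.id: [] for m in model.metabolites}
    for r in model.reactions:
        for met, coeff in r.stoichiometry.items():
            if coeff > 0 or r.lower_bound < 0:
                producers[met].append(r)
    seen, stack, dead = {target}, [target], []
    while stack:
        met = stack.pop()
        if not producers[met]:
            dead.append(met)
            continue
        for r in producers[met]:
            for other, coeff in r.stoichiometry.items():
                consumed = coeff < 0 or r.lower_bound < 0
                if consumed and other not in seen:
                    seen.add(other)
                    stack.append(other)
    return sorted(dead)


def _max_production(model: MetabolicModel, demand: str,
                    disabled: set[str] = frozenset()) -> float:
    overrides = {rid: (0.0, 0.0) for rid in disabled}
    sol = solve_fba(model, demand, sense="max", bound_overrides=overrides)
    return sol.objective_value if sol.optimal else 0.0


def gapfill_weighted_pfba(model: MetabolicModel, pool: UniversalPool,
                          target: str, min_production: float = 1e-3,
                          ) -> list[str]:
    """Introduce a minimal weighted set of pool reactions so the target
    becomes producible at >= min_production.

    Solves min sum_pool w_j |v_j| subject to steady state, bounds and
    production >= min_production over the merged model, then verifies
    minimality of the active set by dropping each member in turn.
    Returns [] when the target is already producible.
    """
    if not model.has_metabolite(target):
        raise KeyError(f"target metabolite {target!r} not in model")
    merged, demand = _merged_with_pool(model, pool, target)
    pool_ids = {r.id for r in pool.reactions}

    if _max_production(merged, demand, disabled=pool_ids) >= min_production:
        return []
    if _max_production(merged, demand) < min_production:
        raise GapfillError(
            f"target {target} unreachable even with the full pool",
            _dead_end_precursors(merged, target))

    # weighted |v| minimization over pool members only (model reactions free)
    problem = FluxProblem.from_model(merged, demand, sense="max")
    j_dem = problem.rxn_index[demand]
    problem.lower[j_dem] = min_production
    import numpy as np
    n = len(problem.rxn_index)
    A = problem.S
    A2 = np.hstack([A, -A])
    b2 = np.zeros(A.shape[0])
    w = np.zeros(n)
    for rid in pool_ids:
        w[problem.rxn_index[rid]] = pool.weights[rid]
    c2 = np.concatenate([w, w])
    lo2 = np.concatenate([np.clip(problem.lower, 0, None),
                          np.clip(-problem.upper, 0, None)])
    hi2 = np.concatenate([np.clip(problem.upper, 0, None),
                          np.clip(-problem.lower, 0, None)])
    from .fba import _solve_lp
    res = _solve_lp(c2, A2, b2, lo2, hi2)
    if res.status != 0:
        raise GapfillError(f"gap-fill LP failed with status {res.status}")
    v = res.x[:n] - res.x[n:]
    added = [rid for rid in sorted(pool_ids)
             if abs(v[problem.rxn_index[rid]]) > ZERO_FLUX_TOL]

    # verify minimality: each member must be necessary given the others
    pruned = True
    while pruned:
        pruned = False
        for rid in list(added):
            others = set(added) - {rid}
            disabled = pool_ids - others
            if _max_production(merged, demand, disabled=disabled) >= min_production:
                added.remove(rid)  # redundant member: drop and re-verify
                pruned = True
                break
    return added


# ---------------------------------------------------------------------------
# Theoretical yield checks
# ---------------------------------------------------------------------------

@dataclass
class YieldCheck:
    substrate: str
    product: str
    fba_yield: float
    theoretical_yield: float

    @property
    def passed(self) -> bool:
        return self.fba_yield <= self.theoretical_yield + 1e-6


def check_max_yield(model: MetabolicModel, substrate: str, product: str,
                    ) -> YieldCheck:
    """Compare the FBA-maximal product yield on a substrate with the
    theoretical maximum from degrees of reduction.

    theoretical = gamma(substrate) / gamma(product) (mol/mol).  The FBA
    side supplies exactly 1 unit of substrate (photons and other organic
    feeds closed) and maximizes a product sink.
    """
    sub = model.metabolite(substrate)
    prod = model.metabolite(product)
    if sub.formula is None or prod.formula is None:
        raise ModelValidationError("both species need elemental formulas")
    gamma_p = degree_of_reduction(prod.formula)
    if gamma_p <= 0:
        raise ModelValidationError(
            f"degree of reduction of {product} is {gamma_p}; yield undefined")
    theoretical = degree_of_reduction(sub.formula) / gamma_p

    probe = model.copy()
    probe.add_reaction(Reaction("__supply_substrate", {substrate: 1.0},
                                0.0, DEFAULT_UPPER))
    probe.add_reaction(Reaction("__sink_product", {product: -1.0},
                                0.0, DEFAULT_UPPER))
    overrides: dict[str, tuple[float, float]] = {}
    closed = ("Photon_PSII_Cyto_tx", "Photon_PSI_Cyto_tx", "Sucrose_Cyto_tx",
              "Glc_Cyto_tx", "Starch_Cyto_tx")
    for r in probe.exchanges():
        if r.id in closed:
            overrides[r.id] = (0.0, 0.0)
    sol = solve_fba(probe, "__sink_product", sense="max",
                    pins={"__supply_substrate": 1.0}, bound_overrides=overrides)
    fba_yield = sol.objective_value if sol.optimal else 0.0
    return YieldCheck(substrate, product, float(fba_yield), float(theoretical))


# ---------------------------------------------------------------------------
# Biomass molecular weight
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassComponent:
    name: str  # drain base name, e.g. "Ala" -> drain id "Ala_biomass"
    metabolite_id: str
    coefficient: float  # mmol per gDW
    formula: str | None

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError(f"component {self.name}: coefficient must be > 0")


@dataclass
class BiomassComposition:
    components: list[BiomassComponent]

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)

    def get(self, name: str) -> BiomassComponent:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)

    def missing_formulas(self) -> list[str]:
        return [c.name for c in self.components if not c.formula]

    def molar_mass(self) -> float:
        """Biomass molar mass in g/mmol: sum of c_i (mmol/gDW) x MW_i
        (g/mol) / 1000."""
        missing = self.missing_formulas()
        if missing:
            raise ModelValidationError(
                f"components without formulas: {', '.join(missing)}")
        return sum(c.coefficient * molecular_weight(c.formula)
                   for c in self.components) / 1000.0

    def with_coefficient(self, name: str, coefficient: float,
                         ) -> "BiomassComposition":
        out = [replace(c, coefficient=coefficient) if c.name == name else c
               for c in self.components]
        if not any(c.name == name for c in self.components):
            raise KeyError(name)
        return BiomassComposition(out)


def rescale_biomass(composition: BiomassComposition) -> BiomassComposition:
    """Uniformly rescale coefficients so the biomass molar mass is exactly
    1 g/mmol.  Idempotent; errors on components without formulas."""
    mass = composition.molar_mass()
    if mass <= 0:
        raise ModelValidationError("biomass molar mass is non-positive")
    scale = 1.0 / mass
    return BiomassComposition(
        [replace(c, coefficient=c.coefficient * scale) for c in composition])


def apply_biomass_composition(model: MetabolicModel,
                              composition: BiomassComposition) -> None:
    """Write composition coefficients into the model's drain reactions
    (drain i consumes its component at c_i per unit biomass flux)."""
    for comp in composition:
        drain_id = f"{comp.name}_biomass"
        drain = model.reaction(drain_id)
        for met_id in list(drain.stoichiometry):
            if drain.stoichiometry[met_id] < 0:
                drain.stoichiometry[met_id] = -comp.coefficient


# ---------------------------------------------------------------------------
# Battery driver
# ---------------------------------------------------------------------------

def run_curation_battery(model: MetabolicModel,
                         composition: BiomassComposition | None = None,
                         ) -> dict:
    """Run every check on a model and return a JSON-serializable report."""
    from .model import check_mass_balance

    report: dict = {"model": model.name, "checks": {}}
    mb = check_mass_balance(model)
    report["checks"]["mass_balance"] = {
        "imbalanced": mb.imbalanced, "skipped": mb.skipped,
        "formula_errors": mb.formula_errors,
        "passed": not mb.imbalanced and not mb.formula_errors,
    }
    for currency in ("ATP", "NADH", "NADPH"):
        cyc = detect_energy_cycles(model, currency)
        report["checks"][f"energy_cycle_{currency}"] = {
            "max_production": cyc.max_production,
            "participants": cyc.participating_reactions,
            "passed": cyc.clean,
        }
    for donor, expected in (("NADH", 1.875), ("succinate", 1.125)):
        try:
            ratio = compute_po_ratio(model, donor)
            report["checks"][f"po_ratio_{donor}"] = {
                "value": ratio, "expected": expected,
                "passed": abs(ratio - expected) < 1e-6,
            }
        except ModelValidationError as exc:
            report["checks"][f"po_ratio_{donor}"] = {
                "value": None, "expected": expected, "passed": False,
                "error": str(exc),
            }
    if composition is not None:
        rescaled = rescale_biomass(composition)
        report["checks"]["biomass_molar_mass"] = {
            "before_g_per_mmol": composition.molar_mass(),
            "after_g_per_mmol": rescaled.molar_mass(),
            "passed": abs(rescaled.molar_mass() - 1.0) < 1e-9,
        }
    report["passed"] = all(c.get("passed") for c in report["checks"].values())
    return report
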