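import itertools

import numpy as np
import pytest

from phytoflux.curation import (
    BiomassComponent,
    BiomassComposition,
    GapfillError,
    ReversibilityRule,
    UniversalPool,
    apply_reversibility_rules,
    check_max_yield,
    compute_po_ratio,
    detect_energy_cycles,
    gapfill_weighted_pfba,
    rescale_biomass,
    run_curation_battery,
)
from phytoflux.fba import solve_fba
from phytoflux.model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

GLUCOSE_MW = 180.156  # 6*12.011 + 12*1.008 + 6*15.999


# ---------------------------------------------------------------------------
# Reversibility rules
# ---------------------------------------------------------------------------

def _rule_model():
    m = MetabolicModel()
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    m.add_metabolite(Metabolite("b_c", compartment="c"))
    m.add_reaction(Reaction("r1", {"a_c": -1, "b_c": 1}, -1000.0, 1000.0))
    m.add_reaction(Reaction("r2", {"b_c": -1, "a_c": 1}, -1000.0, 1000.0))
    return m


@pytest.mark.parametrize("directionality, expected", [
    ("forward", (0.0, 1000.0)),
    ("reverse", (-1000.0, 0.0)),
    ("reversible", (-1000.0, 1000.0)),
])
def test_reversibility_rules_set_directionality(directionality, expected):
    m = _rule_model()
    changed = apply_reversibility_rules(m, [ReversibilityRule("r1", directionality)])
    assert (m.reaction("r1").lower_bound, m.reaction("r1").upper_bound) == expected
    assert (m.reaction("r2").lower_bound, m.reaction("r2").upper_bound) == \
        (-1000.0, 1000.0)
    assert ("r1" in changed) == (directionality != "reversible")


def test_reversibility_rules_never_widen_beyond_defaults():
    m = _rule_model()
    m.reaction("r1").lower_bound, m.reaction("r1").upper_bound = 0.0, 5.0
    apply_reversibility_rules(m, [ReversibilityRule("r*", "reversible")])
    assert m.reaction("r1").upper_bound <= 1000.0
    assert m.reaction("r1").lower_bound == -m.reaction("r1").upper_bound


# ---------------------------------------------------------------------------
# Energy-generating cycles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("currency", ["ATP", "NADH", "NADPH"])
def test_curated_toy_model_has_no_energy_cycles(toy_model, currency):
    report = detect_energy_cycles(toy_model, currency)
    assert report.max_production == pytest.approx(0.0, abs=1e-8)
    assert report.clean


def test_injected_free_phosphorylation_is_detected(toy_model):
    broken = toy_model.copy()
    # costless reverse of ATP hydrolysis: phosphorylation with no proton
    # gradient or redox input
    broken.add_reaction(Reaction(
        "free_atp", {"adp_c": -1, "pi_c": -1, "h_c": -1, "atp_c": 1,
                     "h2o_c": 1}, -1000.0, 1000.0))
    report = detect_energy_cycles(broken, "ATP")
    assert report.max_production > 1e-8
    assert "free_atp" in report.participating_reactions


def test_empty_model_has_no_cycles():
    m = MetabolicModel()
    for base in ("atp", "adp", "pi", "h", "h2o"):
        m.add_metabolite(Metabolite(f"{base}_c", compartment="c"))
    report = detect_energy_cycles(m, "ATP")
    assert report.max_production == pytest.approx(0.0, abs=1e-12)


def test_missing_currency_species_is_configuration_error():
    m = MetabolicModel()
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    with pytest.raises(ModelValidationError):
        detect_energy_cycles(m, "NADPH")


# ---------------------------------------------------------------------------
# P/O ratio
# ---------------------------------------------------------------------------

def test_po_ratios_match_printed_values(toy_model):
    assert compute_po_ratio(toy_model, "NADH") == pytest.approx(1.875, abs=1e-9)
    assert compute_po_ratio(toy_model, "succinate") == pytest.approx(1.125, abs=1e-9)


def test_po_ratio_zero_when_synthase_blocked(toy_model):
    m = toy_model.copy()
    m.reaction("ATPSynth_m").upper_bound = 0.0
    assert compute_po_ratio(m, "NADH") == pytest.approx(0.0, abs=1e-9)


def _mini_etc(p1: float, p2: float, p3: float, h_per_atp: float):
    """Parametric proton-explicit chain: complex I pumps p1 H+ per NADH,
    III pumps p2 per QH2, IV pumps p3 per 2 cyt c; synthase uses h_per_atp."""
    m = MetabolicModel()
    for base in ("nadh", "nad", "q", "qh2", "cytcox", "cytcred", "o2", "h2o",
                 "h", "hims", "atp", "adp", "pi", "succ", "fum"):
        m.add_metabolite(Metabolite(f"{base}_m", compartment="m"))
    m.add_reaction(Reaction("NADH_DH_m", {
        "nadh_m": -1, "q_m": -1, "h_m": -(p1 + 1), "nad_m": 1, "qh2_m": 1,
        "hims_m": p1}))
    m.add_reaction(Reaction("SDH_m", {
        "succ_m": -1, "q_m": -1, "fum_m": 1, "qh2_m": 1}))
    m.add_reaction(Reaction("CIII", {
        "qh2_m": -1, "cytcox_m": -2, "h_m": -2, "q_m": 1, "cytcred_m": 2,
        "hims_m": p2}))
    m.add_reaction(Reaction("CIV", {
        "cytcred_m": -2, "o2_m": -0.5, "h_m": -(p3 + 2), "cytcox_m": 2,
        "h2o_m": 1, "hims_m": p3}))
    m.add_reaction(Reaction("ATPSynth_m", {
        "hims_m": -h_per_atp, "adp_m": -1, "pi_m": -1, "atp_m": 1,
        "h2o_m": 1, "h_m": h_per_atp - 1}))
    m.add_reaction(Reaction("o2_src", {"o2_m": 1}))
    m.add_reaction(Reaction("h2o_sink", {"h2o_m": -1}))
    m.add_reaction(Reaction("h_free", {"h_m": 1}, -1000.0, 1000.0))
    m.objective_reaction = "ATPSynth_m"
    return m


def test_po_ratio_equals_closed_form_for_random_stoichiometries():
    """On any proton-explicit chain, ATP per donor equals
    (H+ translocated per donor) / (H+ consumed per ATP)."""
    rng = np.random.default_rng(7)
    for _ in range(12):
        p1, p2, p3 = rng.integers(1, 7, size=3)
        h_per_atp = rng.choice([8 / 3, 3.0, 10 / 3, 4.0, 14 / 3, 16 / 3])
        model = _mini_etc(float(p1), float(p2), float(p3), float(h_per_atp))
        nadh = compute_po_ratio(model, "NADH")
        succ = compute_po_ratio(model, "succinate")
        assert nadh == pytest.approx((p1 + p2 + p3) / h_per_atp, rel=1e-9)
        assert succ == pytest.approx((p2 + p3) / h_per_atp, rel=1e-9)


def test_po_ratio_diagnoses_blocked_chain(toy_model):
    m = toy_model.copy()
    m.reaction("COX_m").upper_bound = 0.0  # no terminal oxidase
    with pytest.raises(ModelValidationError, match="infeasible"):
        compute_po_ratio(m, "NADH")


# ---------------------------------------------------------------------------
# Weighted-pFBA gap filling
# ---------------------------------------------------------------------------

def _gap_model():
    """a -> b -> c -> d with the middle step missing; demand on d."""
    m = MetabolicModel()
    for mid in ("a_c", "b_c", "c_c", "d_c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("A_Cyto_tx", {"a_c": 1}, 0.0, 10.0, kind="exchange"))
    m.add_reaction(Reaction("step1", {"a_c": -1, "b_c": 1}, 0.0, 10.0))
    m.add_reaction(Reaction("step3", {"c_c": -1, "d_c": 1}, 0.0, 10.0))
    return m


def _pool(entries):
    reactions, weights = [], {}
    for rid, stoich, weight in entries:
        reactions.append(Reaction(rid, stoich, 0.0, 10.0))
        weights[rid] = weight
    return UniversalPool(reactions, weights)


def _exhaustive_minimal_fills(model, pool, target, threshold):
    """Oracle: all inclusion-minimal pool subsets reaching the threshold."""
    from phytoflux.curation import _max_production, _merged_with_pool

    merged, demand = _merged_with_pool(model, pool, target)
    pool_ids = [r.id for r in pool.reactions]
    feasible = []
    for k in range(len(pool_ids) + 1):
        for subset in itertools.combinations(pool_ids, k):
            disabled = set(pool_ids) - set(subset)
            if _max_production(merged, demand, disabled=disabled) >= threshold:
                feasible.append(frozenset(subset))
    return [s for s in feasible
            if not any(o < s for o in feasible)]


def test_gapfill_finds_the_single_missing_step():
    model = _gap_model()
    pool = _pool([
        ("fill_true", {"b_c": -1, "c_c": 1}, 1.0),
        ("fill_irrelevant1", {"a_c": -1, "d_c": 0.0, "b_c": 1}, 1.0),
        ("fill_backward", {"c_c": -1, "b_c": 1}, 1.0),
        ("fill_dead", {"d_c": -1, "a_c": 1}, 1.0),
        ("fill_partial", {"a_c": -1, "c_c": 0.0, "b_c": 1}, 1.0),
    ])
    added = gapfill_weighted_pfba(model, pool, "d_c", min_production=1e-3)
    assert added == ["fill_true"]
    assert _exhaustive_minimal_fills(model, pool, "d_c", 1e-3) == \
        [frozenset({"fill_true"})]


def test_gapfill_returns_empty_when_already_producible():
    model = _gap_model()
    model.add_reaction(Reaction("step2", {"b_c": -1, "c_c": 1}, 0.0, 10.0))
    pool = _pool([("fill_alt", {"b_c": -1, "c_c": 1}, 1.0)])
    assert gapfill_weighted_pfba(model, pool, "d_c") == []


def test_gapfill_prefers_lower_weight_alternative():
    model = _gap_model()
    pool = _pool([
        ("fill_cheap", {"b_c": -1, "c_c": 1}, 1.0),
        ("fill_pricey", {"b_c": -1, "c_c": 1}, 5.0),
    ])
    assert gapfill_weighted_pfba(model, pool, "d_c") == ["fill_cheap"]


def test_gapfill_matches_exhaustive_search_on_two_step_gap():
    model = _gap_model()
    # remove step3 as well: two consecutive gaps, several decoys
    model.reactions = [r for r in model.reactions if r.id != "step3"]
    pool = _pool([
        ("fill_bc", {"b_c": -1, "c_c": 1}, 1.0),
        ("fill_cd", {"c_c": -1, "d_c": 1}, 1.0),
        ("fill_bd_direct", {"b_c": -1, "d_c": 1}, 3.0),
        ("decoy1", {"d_c": -1, "c_c": 1}, 1.0),
        ("decoy2", {"c_c": -1, "a_c": 1}, 1.0),
        ("decoy3", {"a_c": -2, "b_c": 1}, 1.0),
    ])
    added = frozenset(gapfill_weighted_pfba(model, pool, "d_c"))
    minimal = _exhaustive_minimal_fills(model, pool, "d_c", 1e-3)
    assert added in minimal
    # weighted flux of the two unit-weight steps (1+1) beats the direct
    # weight-3 candidate
    assert added == frozenset({"fill_bc", "fill_cd"})


def test_gapfill_unfillable_reports_dead_end_precursors():
    model = _gap_model()
    pool = _pool([("useless", {"a_c": -1, "b_c": 1}, 1.0)])
    with pytest.raises(GapfillError) as err:
        gapfill_weighted_pfba(model, pool, "d_c")
    assert "c_c" in err.value.dead_end_precursors


# ---------------------------------------------------------------------------
# Theoretical yield checks
# ---------------------------------------------------------------------------

def test_sucrose_yield_on_glucose_within_reduction_degree_bound(toy_model):
    check = check_max_yield(toy_model, "glc_c", "suc_c")
    # gamma(glc)=24, gamma(suc)=48: at most 0.5 mol sucrose per mol glucose
    assert check.theoretical_yield == pytest.approx(0.5)
    assert check.passed
    assert check.fba_yield <= 0.5 + 1e-6


def test_mass_creating_bug_fails_yield_check(toy_model):
    broken = toy_model.copy()
    broken.add_reaction(Reaction("dup", {"glc_c": -1, "suc_c": 1}, 0.0, 1000.0))
    check = check_max_yield(broken, "glc_c", "suc_c")
    assert check.fba_yield > check.theoretical_yield + 1e-6
    assert not check.passed


def test_yield_undefined_for_fully_oxidized_product(toy_model):
    with pytest.raises(ModelValidationError, match="yield"):
        check_max_yield(toy_model, "glc_c", "co2_c")


# ---------------------------------------------------------------------------
# Biomass molecular weight
# ---------------------------------------------------------------------------

def _glucose_component(coefficient):
    return BiomassComposition([
        BiomassComponent("Glc", "glc_c", coefficient, "C6H12O6")])


def test_rescale_single_glucose_component():
    rescaled = rescale_biomass(_glucose_component(5.5507))
    assert rescaled.get("Glc").coefficient == pytest.approx(1000 / GLUCOSE_MW,
                                                            rel=1e-6)


def test_rescale_halving_oracle():
    double = rescale_biomass(_glucose_component(2 * 5.5507))
    single = rescale_biomass(_glucose_component(5.5507))
    assert double.get("Glc").coefficient == \
        pytest.approx(single.get("Glc").coefficient, rel=1e-12)


def test_rescale_is_idempotent(composition):
    once = rescale_biomass(composition)
    twice = rescale_biomass(once)
    for a, b in zip(once, twice):
        assert a.coefficient == pytest.approx(b.coefficient, rel=1e-12)


def test_default_composition_weighs_one_gram_per_mmol(composition):
    assert len(composition) == 47
    assert composition.molar_mass() == pytest.approx(1.0, abs=1e-9)


def test_missing_formula_is_an_error():
    comp = BiomassComposition([
        BiomassComponent("Glc", "glc_c", 1.0, "C6H12O6"),
        BiomassComponent("Mystery", "mys_c", 1.0, None)])
    with pytest.raises(ModelValidationError, match="Mystery"):
        rescale_biomass(comp)


# ---------------------------------------------------------------------------
# Battery driver
# ---------------------------------------------------------------------------

def test_curation_battery_passes_on_generated_model(toy_model, composition):
    report = run_curation_battery(toy_model, composition)
    assert report["passed"], report
    assert report["checks"]["po_ratio_NADH"]["value"] == pytest.approx(1.875)
    assert report["checks"]["po_ratio_succinate"]["value"] == pytest.approx(1.125)


def test_curation_battery_is_idempotent(toy_model, composition):
    first = run_curation_battery(toy_model, composition)
    second = run_curation_battery(toy_model, composition)
    assert first == second
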