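import math

import pytest

from phytoflux.conditions import (
    ConditionSpec,
    account_energy_redox,
    compare_fluxes,
    simulate_condition,
    summarize_pathways,
)
from phytoflux.fba import FluxSolution, solve_pfba
from phytoflux.model import MetabolicModel, Metabolite, Reaction


# ---------------------------------------------------------------------------
# ConditionSpec contracts
# ---------------------------------------------------------------------------

def test_soil_preset_cannot_have_sucrose():
    with pytest.raises(ValueError, match="sucrose"):
        ConditionSpec("soil", photon_bound=10.0, sucrose_bound=0.5)


def test_negative_bounds_rejected():
    with pytest.raises(ValueError):
        ConditionSpec("custom", photon_bound=-1.0, sucrose_bound=0.0)


# ---------------------------------------------------------------------------
# Paired simulation: the directional signature of in-vitro growth
# ---------------------------------------------------------------------------

def test_soil_preset_uses_no_sucrose(condition_results):
    soil, _ = condition_results
    assert abs(soil.solution["Sucrose_Cyto_tx"]) <= 1e-8


def test_vitro_preset_imports_sucrose(condition_results):
    _, vitro = condition_results
    assert vitro.solution["Sucrose_Cyto_tx"] > 1e-8


def test_nitrogen_is_half_nitrate_half_ammonium(condition_results):
    for result in condition_results:
        no3 = result.solution["NO3_Cyto_tx"]
        nh4 = result.solution["NH4_Cyto_tx"]
        assert no3 == pytest.approx(nh4, abs=1e-9)
        assert no3 > 0


def test_growth_is_lower_in_vitro(condition_results):
    soil, vitro = condition_results
    assert vitro.solution.objective_value < soil.solution.objective_value


def test_primary_carbon_metabolism_is_lower_in_vitro(condition_results,
                                                     toy_model):
    soil, vitro = condition_results
    ps = summarize_pathways(toy_model, soil.solution)
    pv = summarize_pathways(toy_model, vitro.solution)
    assert pv["Calvin"] < ps["Calvin"]
    assert pv["TCA"] < ps["TCA"]
    assert ps["TCA"] > 1e-8


def test_nitrogen_assimilation_is_higher_in_vitro(condition_results,
                                                  toy_model):
    soil, vitro = condition_results
    ps = summarize_pathways(toy_model, soil.solution)
    pv = summarize_pathways(toy_model, vitro.solution)
    assert pv["GS"] > ps["GS"]
    assert pv["GOGAT"] > ps["GOGAT"]
    # glutamine synthesis outpaces glutamate regeneration in both states
    assert ps["GS_over_GOGAT"] > 1.0
    assert pv["GS_over_GOGAT"] > 1.0


def test_cyclic_electron_flow_share_rises_in_vitro(condition_results,
                                                   toy_model):
    soil, vitro = condition_results
    ps = summarize_pathways(toy_model, soil.solution)
    pv = summarize_pathways(toy_model, vitro.solution)
    assert ps["CEF"] > 1e-8 and pv["CEF"] > 1e-8  # CEF always operational
    assert pv["CEF_over_LEF"] > ps["CEF_over_LEF"]


def test_energy_redox_signature(condition_results, toy_model):
    soil, vitro = condition_results
    es = account_energy_redox(toy_model, soil.solution,
                              soil.solution.objective_value)
    ev = account_energy_redox(toy_model, vitro.solution,
                              vitro.solution.objective_value)
    assert ev["per_biomass"]["ATP_protonpump"] > es["per_biomass"]["ATP_protonpump"]
    assert ev["per_biomass"]["NADPH_net"] < es["per_biomass"]["NADPH_net"]


def test_simulation_solution_is_pfba_tight(condition_results, toy_model):
    # the reported distribution carries no free cycling: re-solving pFBA on
    # the same contextualized model reproduces the total flux
    soil, _ = condition_results
    again = solve_pfba(soil.context_model,
                       pins={"NGAM_c": soil.spec.maintenance_atp},
                       couplings=[{"NO3_Cyto_tx": 1.0, "NH4_Cyto_tx": -1.0}])
    total_a = sum(abs(v) for v in soil.solution.fluxes.values())
    total_b = sum(abs(v) for v in again.fluxes.values())
    assert total_a == pytest.approx(total_b, rel=1e-6)


def test_missing_expression_table_is_an_error(toy_model, composition):
    spec = ConditionSpec("custom", photon_bound=1.0, sucrose_bound=0.0)
    with pytest.raises(ValueError, match="expression"):
        simulate_condition(toy_model, composition, spec)


# ---------------------------------------------------------------------------
# Flux comparison classes
# ---------------------------------------------------------------------------

def _sol(fluxes):
    return FluxSolution("optimal", 1.0, fluxes)


@pytest.mark.parametrize("vs, vv, cls, fc", [
    (2.0, 2.0, "both", 0.0),
    (1.0, 10.0, "both", 1.0),
    (0.5, 0.0, "soil_only", None),
    (0.0, 0.3, "vitro_only", None),
    (0.0, 0.0, "neither", None),
    (1e-9, 1e-9, "neither", None),  # sub-threshold counts as zero
])
def test_compare_fluxes_classes(vs, vv, cls, fc):
    [comparison] = compare_fluxes(_sol({"r": vs}), _sol({"r": vv}))
    assert comparison.cls == cls
    if fc is None:
        assert comparison.log10_fc is None
    else:
        assert comparison.log10_fc == pytest.approx(fc)


def test_compare_fluxes_requires_same_reactions():
    with pytest.raises(ValueError, match="different"):
        compare_fluxes(_sol({"r": 1.0}), _sol({"q": 1.0}))


def test_comparison_classes_partition_toy_reactions(condition_results,
                                                    toy_model):
    soil, vitro = condition_results
    comparisons = compare_fluxes(soil.solution, vitro.solution)
    assert len(comparisons) == len(toy_model.reactions)
    assert {c.cls for c in comparisons} <= \
        {"both", "vitro_only", "soil_only", "neither"}
    for c in comparisons:
        assert (c.log10_fc is not None) == (c.cls == "both")
        if c.cls == "both":
            assert c.log10_fc == pytest.approx(
                math.log10(abs(c.flux_vitro) / abs(c.flux_soil)))


# ---------------------------------------------------------------------------
# Energy accounting arithmetic
# ---------------------------------------------------------------------------

def _two_synthase_model():
    m = MetabolicModel()
    for mid in ("atp_p", "adp_p", "hlum_p"):
        m.add_metabolite(Metabolite(mid, compartment="p"))
    for mid in ("atp_m", "adp_m", "hims_m"):
        m.add_metabolite(Metabolite(mid, compartment="m"))
    m.add_reaction(Reaction("ATPSynth_p", {"hlum_p": -4, "adp_p": -1,
                                           "atp_p": 1}))
    m.add_reaction(Reaction("ATPSynth_m", {"hims_m": -4, "adp_m": -1,
                                           "atp_m": 1}))
    m.pathway_tags = {"ATPSynth_p": "atp_synthase",
                      "ATPSynth_m": "atp_synthase"}
    return m


def test_atp_protonpump_sums_synthase_fluxes():
    m = _two_synthase_model()
    sol = _sol({"ATPSynth_p": 3.0, "ATPSynth_m": 1.0})
    account = account_energy_redox(m, sol, biomass_flux=0.5)
    assert account["ATP_protonpump"] == pytest.approx(4.0)
    assert account["per_biomass"]["ATP_protonpump"] == pytest.approx(8.0)


def test_zero_etc_flux_gives_zero_pump_atp():
    m = _two_synthase_model()
    account = account_energy_redox(m, _sol({"ATPSynth_p": 0.0,
                                            "ATPSynth_m": 0.0}), 1.0)
    assert account["ATP_protonpump"] == 0.0


def test_zero_biomass_flags_normalization():
    m = _two_synthase_model()
    account = account_energy_redox(m, _sol({"ATPSynth_p": 1.0,
                                            "ATPSynth_m": 0.0}), 0.0)
    assert account["per_biomass"] is None
    assert "warning" in account


# ---------------------------------------------------------------------------
# Pathway summaries
# ---------------------------------------------------------------------------

def test_dark_solution_has_no_electron_flow(toy_model):
    overrides = {r.id: (max(r.lower_bound, -1.0), min(r.upper_bound, 1.0))
                 for r in toy_model.exchanges()}
    overrides["Photon_PSII_Cyto_tx"] = (0.0, 0.0)
    overrides["Photon_PSI_Cyto_tx"] = (0.0, 0.0)
    overrides["Sucrose_Cyto_tx"] = (0.0, 1.0)
    sol = solve_pfba(toy_model, bound_overrides=overrides)
    summary = summarize_pathways(toy_model, sol)
    assert summary["LEF"] == pytest.approx(0.0, abs=1e-8)
    assert summary["CEF"] == pytest.approx(0.0, abs=1e-8)


def test_unknown_pathway_tag_is_error(toy_model, condition_results):
    soil, _ = condition_results
    with pytest.raises(KeyError, match="nonexistent"):
        summarize_pathways(toy_model, soil.solution,
                           {"bogus": "nonexistent"})
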