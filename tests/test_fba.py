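import numpy as np
import pytest

from phytoflux.fba import (
    ValidationCase,
    fifty_fifty_nitrogen,
    predict_growth_rates,
    solve_fba,
    solve_pfba,
)
from phytoflux.model import MetabolicModel, Metabolite, Reaction


def chain_model(uptake=1.0):
    """Aext -(uptake)-> A -> B -> biomass sink."""
    m = MetabolicModel()
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("A_Cyto_tx", {"a_c": 1}, 0.0, uptake,
                            kind="exchange"))
    m.add_reaction(Reaction("conv", {"a_c": -1, "b_c": 1}, 0.0, 1000.0))
    m.add_reaction(Reaction("Biomass", {"b_c": -1}, 0.0, 1000.0,
                            kind="biomass"))
    m.objective_reaction = "Biomass"
    return m


def branched_model():
    """Two routes with different yields plus a side tax reaction."""
    m = MetabolicModel()
    for mid in ("s_c", "x_c", "y_c", "p_c"):
        m.add_metabolite(Metabolite(mid, compartment="c"))
    m.add_reaction(Reaction("S_Cyto_tx", {"s_c": 1}, 0.0, 2.0, kind="exchange"))
    m.add_reaction(Reaction("hi_yield", {"s_c": -1, "x_c": 1}, 0.0, 1.2))
    m.add_reaction(Reaction("lo_yield", {"s_c": -2, "y_c": 1}, 0.0, 5.0))
    m.add_reaction(Reaction("fin_x", {"x_c": -1, "p_c": 1}, 0.0, 5.0))
    m.add_reaction(Reaction("fin_y", {"y_c": -1, "p_c": 0.8}, 0.0, 5.0))
    m.add_reaction(Reaction("sink", {"p_c": -1}, 0.0, 10.0, kind="biomass"))
    m.objective_reaction = "sink"
    return m


def test_linear_chain_optimum_is_uptake_bound():
    sol = solve_fba(chain_model(uptake=1.0))
    assert sol.optimal and sol.objective_value == pytest.approx(1.0)


def test_all_exchanges_closed_gives_zero():
    sol = solve_fba(chain_model(), bound_overrides={"A_Cyto_tx": (0.0, 0.0)})
    assert sol.optimal and sol.objective_value == pytest.approx(0.0)


def test_unbounded_objective_reported_explicitly():
    m = chain_model()
    m.reaction("Biomass").upper_bound = np.inf
    m.add_reaction(Reaction("free_b", {"b_c": 1}, 0.0, np.inf))
    sol = solve_fba(m)
    assert sol.status == "unbounded" and sol.objective_value is None


def test_infeasible_reported():
    m = chain_model()
    sol = solve_fba(m, pins={"Biomass": 5.0})  # demands more than uptake
    assert sol.status == "infeasible"


def test_branched_optimum_matches_vertex_enumeration(vertex_oracle):
    m = branched_model()
    sol = solve_fba(m)
    best = max(v["sink"] for v in vertex_oracle(m))
    assert sol.objective_value == pytest.approx(best, abs=1e-9)


def test_steady_state_and_bounds_hold_on_toy_model(toy_model):
    from phytoflux.model import build_stoichiometric_matrix

    overrides = {r.id: (r.lower_bound, min(r.upper_bound, 10.0))
                 for r in toy_model.exchanges()}
    sol = solve_pfba(toy_model, bound_overrides=overrides)
    assert sol.optimal
    S, met_index, rxn_index = build_stoichiometric_matrix(toy_model)
    v = np.zeros(len(rxn_index))
    for rid, j in rxn_index.items():
        v[j] = sol.fluxes[rid]
    assert np.max(np.abs(S @ v)) < 1e-6
    for r in toy_model.reactions:
        lb, ub = overrides.get(r.id, (r.lower_bound, r.upper_bound))
        assert lb - 1e-6 <= sol.fluxes[r.id] <= ub + 1e-6


def test_fba_agrees_with_cobra_on_toy_model(toy_model):
    """Independent cross-check: cobrapy + GLPK solves the identical LP."""
    from phytoflux.io import to_cobra

    cm = to_cobra(toy_model)
    expected = cm.optimize().objective_value
    ours = solve_fba(toy_model).objective_value
    assert ours == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def test_pfba_silences_futile_cycle():
    m = chain_model()
    # a free reversible loop parallel to the chain
    m.add_reaction(Reaction("loop_fwd", {"a_c": -1, "b_c": 1}, -1000.0, 1000.0))
    sol = solve_pfba(m)
    assert sol.objective_value == pytest.approx(1.0)
    assert abs(sol.fluxes["loop_fwd"]) + abs(sol.fluxes["conv"]) == \
        pytest.approx(1.0)  # no extra cycling on top of the needed flux


def test_pfba_total_flux_not_above_any_optimal_vertex(vertex_oracle):
    m = branched_model()
    sol = solve_pfba(m)
    opt = solve_fba(m).objective_value
    total = sum(abs(v) for v in sol.fluxes.values())
    optimal_vertices = [v for v in vertex_oracle(m)
                        if v["sink"] >= opt - 1e-9]
    assert optimal_vertices
    assert total <= min(sum(abs(x) for x in v.values())
                        for v in optimal_vertices) + 1e-6


def test_pfba_unique_optimum_equals_fba():
    m = chain_model()
    fba = solve_fba(m)
    pfba = solve_pfba(m)
    for rid in fba.fluxes:
        assert pfba.fluxes[rid] == pytest.approx(fba.fluxes[rid], abs=1e-6)


# ---------------------------------------------------------------------------
# LP structure properties (fuzzed, seeded)
# ---------------------------------------------------------------------------

def test_tightening_bounds_never_increases_optimum():
    rng = np.random.default_rng(0)
    m = branched_model()
    base = solve_fba(m).objective_value
    ids = [r.id for r in m.reactions]
    for _ in range(20):
        rid = ids[rng.integers(len(ids))]
        r = m.reaction(rid)
        shrink = rng.uniform(0.3, 1.0)
        sol = solve_fba(m, bound_overrides={
            rid: (r.lower_bound * shrink, r.upper_bound * shrink)})
        value = sol.objective_value if sol.optimal else 0.0
        assert value <= base + 1e-9


def test_scaling_all_bounds_scales_optimum():
    m = branched_model()
    base = solve_fba(m).objective_value
    for k in (0.5, 2.0, 7.5):
        overrides = {r.id: (r.lower_bound * k, r.upper_bound * k)
                     for r in m.reactions if np.isfinite(r.upper_bound)}
        scaled = solve_fba(m, bound_overrides=overrides).objective_value
        assert scaled == pytest.approx(k * base, rel=1e-9)


# ---------------------------------------------------------------------------
# CO2-constrained growth validation
# ---------------------------------------------------------------------------

def test_growth_scales_linearly_with_co2(toy_model):
    cases = [ValidationCase("wt", 0.4), ValidationCase("hi", 0.8),
             ValidationCase("none", 0.0)]
    table, _ = predict_growth_rates(toy_model, cases)
    by_label = table.set_index("line_label")["predicted_growth"]
    assert by_label["none"] == pytest.approx(0.0, abs=1e-9)
    assert by_label["hi"] == pytest.approx(2 * by_label["wt"], rel=1e-6)


def test_growth_correlates_with_observations(toy_model):
    cases = [ValidationCase("a", 0.2, observed_growth=0.1),
             ValidationCase("b", 0.4, observed_growth=0.21),
             ValidationCase("c", 0.6, observed_growth=0.31)]
    table, pearson = predict_growth_rates(toy_model, cases)
    assert table["status"].eq("optimal").all()
    assert pearson == pytest.approx(1.0, abs=1e-3)  # linear regime


def test_nitrogen_enters_half_nitrate_half_ammonium(toy_model):
    table, _ = predict_growth_rates(toy_model, [ValidationCase("wt", 0.6)])
    assert table.loc[0, "predicted_growth"] > 0
    sol = solve_fba(toy_model, pins={"CO2_Cyto_tx": 0.6},
                    bound_overrides={rid: (0.0, 0.0) for rid in
                                     ("Sucrose_Cyto_tx", "Glc_Cyto_tx",
                                      "Starch_Cyto_tx")},
                    couplings=[fifty_fifty_nitrogen(toy_model)])
    no3, nh4 = sol.fluxes["NO3_Cyto_tx"], sol.fluxes["NH4_Cyto_tx"]
    assert no3 == pytest.approx(nh4, abs=1e-9)
    assert no3 > 0


def test_infeasible_case_recorded_and_run_continues(toy_model):
    cases = [ValidationCase("ok", 0.3), ValidationCase("impossible", 900.0)]
    table, _ = predict_growth_rates(toy_model, cases)
    assert list(table["status"]) == ["optimal", "infeasible"]
    assert table.loc[1, "predicted_growth"] is None or \
        np.isnan(table.loc[1, "predicted_growth"])
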