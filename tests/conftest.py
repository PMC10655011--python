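"""Shared fixtures: the synthetic study (seed 1) and small LP oracles."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from phytoflux.conditions import simulate_condition
from phytoflux.model import build_stoichiometric_matrix
from phytoflux.synthetic import (
    GeneratorConfig,
    default_biomass_composition,
    generate_amino_acid_tables,
    generate_condition_specs,
    generate_expression_profiles,
    generate_toy_plant_model,
)

SEED = 1


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=SEED)


@pytest.fixture(scope="session")
def toy_model(config):
    return generate_toy_plant_model(config)


@pytest.fixture(scope="session")
def composition(config):
    return default_biomass_composition(config)


@pytest.fixture(scope="session")
def expression_tables(toy_model, config):
    return generate_expression_profiles(toy_model, config)


@pytest.fixture(scope="session")
def amino_acid_tables(config):
    return generate_amino_acid_tables(config)


@pytest.fixture(scope="session")
def condition_results(toy_model, composition, config):
    """Soil and in-vitro pFBA results of the paired simulation."""
    soil_spec, vitro_spec = generate_condition_specs(toy_model, config)
    soil = simulate_condition(toy_model, composition, soil_spec)
    vitro = simulate_condition(toy_model, composition, vitro_spec)
    return soil, vitro


# ---------------------------------------------------------------------------
# Independent LP oracle: exhaustive vertex enumeration
# ---------------------------------------------------------------------------

def enumerate_vertices(model, extra_rows=()):
    """All basic feasible solutions of {S v = 0, l <= v <= u}.

    Exponential; only for fixture models with <= ~10 reactions.  Returns a
    list of flux vectors (dicts).  Independent of the LP solver: vertices
    come from solving square linear systems over active-constraint sets.
    """
    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    A = S
    for row in extra_rows:
        extra = np.zeros((1, len(rxn_index)))
        for rid, coeff in row.items():
            extra[0, rxn_index[rid]] = coeff
        A = np.vstack([A, extra])
    n = len(rxn_index)
    lower = np.empty(n)
    upper = np.empty(n)
    for r in model.reactions:
        lower[rxn_index[r.id]] = r.lower_bound
        upper[rxn_index[r.id]] = r.upper_bound
    rank = np.linalg.matrix_rank(A)
    inv = {j: rid for rid, j in rxn_index.items()}
    vertices = []
    for nonbasic in combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in nonbasic]
        A_B = A[:, basic]
        if np.linalg.matrix_rank(A_B) < rank:
            continue
        for pattern in product((0, 1), repeat=len(nonbasic)):
            v = np.zeros(n)
            for j, at_upper in zip(nonbasic, pattern):
                v[j] = upper[j] if at_upper else lower[j]
            rhs = -A[:, list(nonbasic)] @ v[list(nonbasic)]
            sol, *_ = np.linalg.lstsq(A_B, rhs, rcond=None)
            if np.max(np.abs(A_B @ sol - rhs)) > 1e-9:
                continue
            v[basic] = sol
            if np.all(v >= lower - 1e-9) and np.all(v <= upper + 1e-9):
                vertices.append({inv[j]: v[j] for j in range(n)})
    return vertices


@pytest.fixture(scope="session")
def vertex_oracle():
    return enumerate_vertices
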