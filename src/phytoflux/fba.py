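"""Flux balance analysis core: FBA, parsimonious FBA, growth validation.

The LP is the standard steady-state problem

    maximize  c' v
    s.t.      S v = 0          (every declared metabolite)
              A v = 0          (optional coupling rows, e.g. 50/50 nitrogen)
              v_min <= v <= v_max

solved with HiGHS through :func:`scipy.optimize.linprog`.  The backend sits
behind :func:`_solve_lp` so an alternative solver can be swapped in; all
reported numbers must be backend-independent to ~1e-6.

Flux distributions that feed downstream comparisons come from pFBA (D10):
plain FBA flux vectors are degenerate and per-reaction fold changes would
otherwise be solver-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import (
    FEASIBILITY_TOL,
    MetabolicModel,
    build_stoichiometric_matrix,
)

__all__ = [
    "FluxProblem",
    "FluxSolution",
    "ValidationCase",
    "solve_fba",
    "solve_pfba",
    "predict_growth_rates",
    "InfeasibleProblemError",
]

_PFBA_OPT_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxProblem:
    """An assembled LP: matrix, bounds, objective and equality pins."""

    model: MetabolicModel
    S: np.ndarray
    met_index: dict[str, int]
    rxn_index: dict[str, int]
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    #: extra equality rows over fluxes (each a dict rxn_id -> coefficient)
    couplings: list[dict[str, float]] = field(default_factory=list)

    @classmethod
    def from_model(cls, model: MetabolicModel, objective: str,
                   sense: str = "max",
                   pins: dict[str, float] | None = None,
                   bound_overrides: dict[str, tuple[float, float]] | None = None,
                   couplings: list[dict[str, float]] | None = None,
                   ) -> "FluxProblem":
        S, met_index, rxn_index = build_stoichiometric_matrix(model)
        n = len(rxn_index)
        lower = np.empty(n)
        upper = np.empty(n)
        for r in model.reactions:
            j = rxn_index[r.id]
            lower[j], upper[j] = r.lower_bound, r.upper_bound
        if bound_overrides:
            for rid, (lb, ub) in bound_overrides.items():
                j = rxn_index[rid]
                lower[j], upper[j] = lb, ub
        if pins:
            for rid, value in pins.items():
                j = rxn_index[rid]
                if value < lower[j] - FEASIBILITY_TOL or value > upper[j] + FEASIBILITY_TOL:
                    raise ValueError(
                        f"pin {rid}={value} outside bounds [{lower[j]}, {upper[j]}]")
                lower[j] = upper[j] = value
        c = np.zeros(n)
        if objective not in rxn_index:
            raise KeyError(f"objective reaction {objective!r} not in model")
        c[rxn_index[objective]] = 1.0 if sense == "max" else -1.0
        return cls(model, S, met_index, rxn_index, lower, upper, c,
                   couplings=list(couplings or []))

    def coupling_matrix(self) -> np.ndarray | None:
        if not self.couplings:
            return None
        A = np.zeros((len(self.couplings), len(self.rxn_index)))
        for i, row in enumerate(self.couplings):
            for rid, coeff in row.items():
                A[i, self.rxn_index[rid]] = coeff
        return A


def _solve_lp(c: np.ndarray, A_eq: np.ndarray, b_eq: np.ndarray,
              lower: np.ndarray, upper: np.ndarray):
    """Minimize c'v subject to A_eq v = b_eq, lower <= v <= upper."""
    bounds = list(zip(lower, upper))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def _assemble(problem: FluxProblem) -> tuple[np.ndarray, np.ndarray]:
    A = problem.S
    extra = problem.coupling_matrix()
    if extra is not None:
        A = np.vstack([A, extra])
    b = np.zeros(A.shape[0])
    return A, b


def solve_fba(model: MetabolicModel, objective: str | None = None,
              sense: str = "max",
              pins: dict[str, float] | None = None,
              bound_overrides: dict[str, tuple[float, float]] | None = None,
              couplings: list[dict[str, float]] | None = None,
              ) -> FluxSolution:
    """Flux balance analysis; returns an explicit status, never a silent
    large number for an unbounded objective."""
    objective = objective or model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given and model has none")
    problem = FluxProblem.from_model(model, objective, sense=sense, pins=pins,
                                     bound_overrides=bound_overrides,
                                     couplings=couplings)
    return solve_problem(problem, sense=sense)


def solve_problem(problem: FluxProblem, sense: str = "max") -> FluxSolution:
    A, b = _assemble(problem)
    # linprog minimizes; FluxProblem stores c with the sign already folded
    # in for max problems, so always minimize -objective.
    res = _solve_lp(-problem.objective, A, b, problem.lower, problem.upper)
    if res.status == 3:
        return FluxSolution("unbounded", None)
    if res.status != 0:
        return FluxSolution("infeasible", None)
    inv = {j: rid for rid, j in problem.rxn_index.items()}
    fluxes = {inv[j]: float(res.x[j]) for j in range(len(res.x))}
    return FluxSolution("optimal", float(problem.objective @ res.x), fluxes)


def solve_pfba(model: MetabolicModel, objective: str | None = None,
               sense: str = "max",
               pins: dict[str, float] | None = None,
               bound_overrides: dict[str, tuple[float, float]] | None = None,
               couplings: list[dict[str, float]] | None = None,
               weights: dict[str, float] | None = None,
               ) -> FluxSolution:
    """Parsimonious FBA: pin the objective at its FBA optimum, then
    minimize the (optionally weighted) total absolute flux.

    The |v| terms are linearized by the standard v = v+ - v- split with
    v+, v- >= 0.  Returns a solution attaining both optima.
    """
    objective = objective or model.objective_reaction
    problem = FluxProblem.from_model(model, objective, sense=sense, pins=pins,
                                     bound_overrides=bound_overrides,
                                     couplings=couplings)
    first = solve_problem(problem, sense=sense)
    if not first.optimal:
        return first
    opt = first.objective_value

    n = len(problem.rxn_index)
    A, b = _assemble(problem)
    m = A.shape[0]
    # pin the objective value (both senses: c'v == opt)
    A2 = np.vstack([np.hstack([A, -A]),
                    np.hstack([problem.objective, -problem.objective])[None, :]])
    b2 = np.concatenate([b, [opt]])
    w = np.ones(n)
    if weights:
        for rid, wj in weights.items():
            w[problem.rxn_index[rid]] = wj
    c2 = np.concatenate([w, w])
    lo2 = np.concatenate([np.clip(problem.lower, 0, None),
                          np.clip(-problem.upper, 0, None)])
    hi2 = np.concatenate([np.clip(problem.upper, 0, None),
                          np.clip(-problem.lower, 0, None)])
    res = _solve_lp(c2, A2, b2, lo2, hi2)
    if res.status != 0:
        # tiny numerical slack on the pinned optimum, retry once
        b2[-1] = opt - np.sign(opt or 1.0) * _PFBA_OPT_TOL
        res = _solve_lp(c2, A2, b2, lo2, hi2)
        if res.status != 0:
            raise InfeasibleProblemError(
                f"pFBA restriction infeasible (status {res.status})")
    v = res.x[:n] - res.x[n:]
    inv = {j: rid for rid, j in problem.rxn_index.items()}
    fluxes = {inv[j]: float(v[j]) for j in range(n)}
    return FluxSolution("optimal", float(problem.objective @ v), fluxes)


# ---------------------------------------------------------------------------
# CO2-constrained growth validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationCase:
    line_label: str
    co2_fixation_rate: float
    observed_growth: float | None = None

    def __post_init__(self):
        if self.co2_fixation_rate < 0:
            raise ValueError("co2_fixation_rate must be >= 0")


def fifty_fifty_nitrogen(model: MetabolicModel,
                         nitrate_exchange: str = "NO3_Cyto_tx",
                         ammonium_exchange: str = "NH4_Cyto_tx",
                         ) -> dict[str, float]:
    """Equality coupling v_NO3 - v_NH4 = 0: nitrogen enters half as nitrate
    and half as ammonium while the total floats with growth."""
    for rid in (nitrate_exchange, ammonium_exchange):
        if not model.has_reaction(rid):
            raise KeyError(f"nitrogen exchange {rid} not in model")
    return {nitrate_exchange: 1.0, ammonium_exchange: -1.0}


ORGANIC_EXCHANGES = ("Sucrose_Cyto_tx", "Glc_Cyto_tx", "Starch_Cyto_tx")
PHOTON_EXCHANGES = ("Photon_PSII_Cyto_tx", "Photon_PSI_Cyto_tx")


def predict_growth_rates(model: MetabolicModel,
                         cases: list[ValidationCase],
                         photon_open: bool = True,
                         co2_exchange: str = "CO2_Cyto_tx",
                         photon_bound: float = 1000.0,
                         ):
    """Predict growth for a panel of lines with known CO2 fixation capacity.

    Per case: organic carbon sources closed, photons open, nitrogen uptake
    coupled 50% nitrate / 50% ammonium, CO2 uptake pinned to the line's
    fixation rate, biomass maximized.  Infeasible cases are recorded and
    the run continues.  Returns (rows, pearson_r) where pearson_r is None
    unless >=2 cases carry observations.
    """
    import pandas as pd

    couplings = [fifty_fifty_nitrogen(model)]
    overrides: dict[str, tuple[float, float]] = {}
    for rid in ORGANIC_EXCHANGES:
        if model.has_reaction(rid):
            overrides[rid] = (0.0, 0.0)
    for rid in PHOTON_EXCHANGES:
        if model.has_reaction(rid):
            overrides[rid] = (0.0, photon_bound if photon_open else 0.0)

    rows = []
    for case in cases:
        sol = solve_fba(model, model.objective_reaction, sense="max",
                        pins={co2_exchange: case.co2_fixation_rate},
                        bound_overrides=overrides, couplings=couplings)
        rows.append({
            "line_label": case.line_label,
            "co2_fixation_rate": case.co2_fixation_rate,
            "predicted_growth": sol.objective_value if sol.optimal else None,
            "status": sol.status,
            "observed_growth": case.observed_growth,
        })
    table = pd.DataFrame(rows)
    observed = table.dropna(subset=["predicted_growth", "observed_growth"])
    pearson = None
    if len(observed) >= 2 and observed["predicted_growth"].std() > 0:
        pearson = float(np.corrcoef(observed["predicted_growth"],
                                    observed["observed_growth"])[0, 1])
    return table, pearson
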