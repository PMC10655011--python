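"""Domain types for compartmentalized stoichiometric models.

Conventions
-----------
* Metabolite ids carry a compartment suffix: ``_c`` cytosol, ``_m``
  mitochondrion, ``_p`` plastid, ``_x`` peroxisome, ``_v`` vacuole.
* Exchange reactions end in ``_Cyto_tx``, contain exactly one metabolite
  and are written import-positive: positive flux means uptake, so the
  upper bound encodes availability (D1).  There are no boundary species:
  external pools are implicitly unconstrained (D3).
* Biomass drain reactions end in ``_biomass``.
* Transport reactions span exactly two compartments, one of which is the
  cytosol (the hub convention of plant GEMs).

Default bounds when a reaction does not state its own: irreversible
``[0, 1000]``, reversible ``[-1000, 1000]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .formulas import FormulaError, parse_formula

__all__ = [
    "COMPARTMENTS",
    "DEFAULT_UPPER",
    "FEASIBILITY_TOL",
    "ZERO_FLUX_TOL",
    "GPRExpr",
    "parse_gpr",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ModelValidationError",
    "build_stoichiometric_matrix",
    "check_mass_balance",
]

COMPARTMENTS = ("c", "m", "p", "x", "v", "external")

#: Default bound magnitude for reactions that do not state bounds.
DEFAULT_UPPER = 1000.0
#: Feasibility / mass-balance tolerance (D2).
FEASIBILITY_TOL = 1e-9
#: Threshold below which a reported flux counts as zero (D2).
ZERO_FLUX_TOL = 1e-8

EXCHANGE_SUFFIX = "_Cyto_tx"
BIOMASS_DRAIN_SUFFIX = "_biomass"


class ModelValidationError(ValueError):
    """A model (or a piece of one) violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpr:
    """Boolean gene tree: a leaf gene id, or AND/OR over >=2 children."""

    op: str  # "gene", "and", "or"
    gene: str | None = None
    children: tuple["GPRExpr", ...] = ()

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene:
                raise ModelValidationError("GPR leaf with empty gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ModelValidationError(f"GPR {self.op} needs >=2 children")
        else:
            raise ModelValidationError(f"unknown GPR operator {self.op!r}")

    @staticmethod
    def leaf(gene: str) -> "GPRExpr":
        return GPRExpr("gene", gene=gene)

    @staticmethod
    def and_(*children: "GPRExpr") -> "GPRExpr":
        return GPRExpr("and", children=tuple(children))

    @staticmethod
    def or_(*children: "GPRExpr") -> "GPRExpr":
        return GPRExpr("or", children=tuple(children))

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op != "gene":
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize_gpr(text: str) -> list[str]:
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_gpr(text: str) -> GPRExpr | None:
    """Parse a boolean gene rule such as ``"(g1 or g2) and g3"``.

    Returns ``None`` for an empty rule.  ``and`` binds tighter than ``or``.
    """
    tokens = _tokenize_gpr(text or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GPRExpr:
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRExpr.or_(*terms)

    def parse_and() -> GPRExpr:
        nonlocal pos
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPRExpr.and_(*factors)

    def parse_atom() -> GPRExpr:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ModelValidationError(f"unexpected end of GPR rule {text!r}")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise ModelValidationError(f"unbalanced parentheses in GPR {text!r}")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelValidationError(f"unexpected token {tok!r} in GPR {text!r}")
        pos += 1
        return GPRExpr.leaf(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise ModelValidationError(f"trailing tokens in GPR {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}")
        if self.compartment != "external" and not self.id.endswith("_" + self.compartment):
            raise ModelValidationError(
                f"metabolite {self.id}: id must end with _{self.compartment}")
        if self.formula is not None:
            parse_formula(self.formula)  # raises FormulaError if malformed

    def element_counts(self) -> dict[str, int] | None:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


REACTION_KINDS = ("biochemical", "transport", "exchange", "biomass_drain", "biomass")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: GPRExpr | None = None
    kind: str = "biochemical"
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} > upper "
                f"bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def metabolite_ids(self) -> list[str]:
        return list(self.stoichiometry)

    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _compartment_of(met_id: str) -> str | None:
    for code in ("c", "m", "p", "x", "v"):
        if met_id.endswith("_" + code):
            return code
    return None


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction: str | None = None
    compartments: set[str] = field(default_factory=set)
    name: str = ""
    #: reaction id -> pathway tag, used by condition analysis
    pathway_tags: dict[str, str] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index()[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index()[rxn_id]

    def _met_index(self) -> dict[str, Metabolite]:
        idx = getattr(self, "_mets", None)
        if idx is None or len(idx) != len(self.metabolites):
            idx = {m.id: m for m in self.metabolites}
            object.__setattr__(self, "_mets", idx)
        return idx

    def _rxn_index(self) -> dict[str, Reaction]:
        idx = getattr(self, "_rxns", None)
        if idx is None or len(idx) != len(self.reactions):
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxns", idx)
        return idx

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def biomass_drains(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "biomass_drain"]

    # -- mutation helpers --------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites.append(met)
        if met.compartment != "external":
            self.compartments.add(met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if not self.has_metabolite(met_id):
                raise ModelValidationError(
                    f"reaction {rxn.id}: unknown metabolite {met_id}")
        self.reactions.append(rxn)

    def copy(self) -> "MetabolicModel":
        import copy as _copy
        return _copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError."""
        seen_m: set[str] = set()
        for met in self.metabolites:
            if met.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {met.id}")
            seen_m.add(met.id)
        seen_r: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {rxn.id}")
            seen_r.add(rxn.id)
            for met_id in rxn.stoichiometry:
                if met_id not in seen_m:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: stoichiometry key {met_id} does not "
                        "resolve to a declared metabolite")
            is_exchange_id = rxn.id.endswith(EXCHANGE_SUFFIX)
            if (rxn.kind == "exchange") != is_exchange_id:
                raise ModelValidationError(
                    f"reaction {rxn.id}: kind=exchange iff id ends {EXCHANGE_SUFFIX}")
            is_drain_id = rxn.id.endswith(BIOMASS_DRAIN_SUFFIX)
            if (rxn.kind == "biomass_drain") != is_drain_id:
                raise ModelValidationError(
                    f"reaction {rxn.id}: kind=biomass_drain iff id ends "
                    f"{BIOMASS_DRAIN_SUFFIX}")
            if rxn.kind == "exchange" and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange {rxn.id} must have exactly one metabolite")
            if rxn.kind == "transport":
                comps = {_compartment_of(m) for m in rxn.stoichiometry}
                comps.discard(None)
                if len(comps) != 2 or "c" not in comps:
                    raise ModelValidationError(
                        f"transport {rxn.id} must span exactly two compartments, "
                        f"one of which is cytosol (got {sorted(comps)})")
        if self.objective_reaction is not None and self.objective_reaction not in seen_r:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction} not in model")


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Dense S (metabolites x reactions) plus id -> index maps.

    ``S[i, j]`` is the coefficient of metabolite i in reaction j (negative =
    consumed).  Every declared metabolite is a row; exchanges therefore have
    a single nonzero entry (external pools are not rows, D3).
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for r in model.reactions:
        j = rxn_index[r.id]
        for met_id, coeff in r.stoichiometry.items():
            S[met_index[met_id], j] += coeff
    return S, met_index, rxn_index


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------

@dataclass
class MassBalanceReport:
    #: reaction id -> element -> residual (sum of coeff * count)
    imbalanced: dict[str, dict[str, float]]
    #: reactions skipped because a participant has no formula
    skipped: list[str]
    #: metabolite id -> error message for unparseable formulas
    formula_errors: dict[str, str]

    @property
    def imbalanced_ids(self) -> list[str]:
        return list(self.imbalanced)


def check_mass_balance(model: MetabolicModel, tol: float = FEASIBILITY_TOL,
                       ) -> MassBalanceReport:
    """Elemental balance of every biochemical/transport reaction.

    Exchange, biomass-drain and biomass reactions are exempt (they are the
    model's boundary).  Reactions touching a metabolite without a formula
    are skipped and reported separately rather than failing.
    """
    counts: dict[str, dict[str, int] | None] = {}
    formula_errors: dict[str, str] = {}
    for met in model.metabolites:
        if met.formula is None:
            counts[met.id] = None
            continue
        try:
            counts[met.id] = parse_formula(met.formula)
        except FormulaError as exc:
            counts[met.id] = None
            formula_errors[met.id] = str(exc)

    imbalanced: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for rxn in model.reactions:
        if rxn.kind in ("exchange", "biomass_drain", "biomass"):
            continue
        if any(counts[m] is None for m in rxn.stoichiometry):
            skipped.append(rxn.id)
            continue
        residual: dict[str, float] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            for el, n in counts[met_id].items():
                residual[el] = residual.get(el, 0.0) + coeff * n
        residual = {el: v for el, v in residual.items() if abs(v) > tol}
        if residual:
            imbalanced[rxn.id] = residual
    return MassBalanceReport(imbalanced, skipped, formula_errors)
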