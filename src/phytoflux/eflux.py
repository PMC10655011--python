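"""E-Flux contextualization and free amino-acid biomass updates.

E-Flux turns replicate FPKM tables into condition-specific reaction
bounds: each gene gets an activity score log2(mean FPKM + 1) (mean over
replicates, then log; D11); GPR trees are evaluated with OR = sum of
children and AND = min of children (the original E-Flux convention, D12);
reaction-level scores are normalized by the maximum over scored reactions
in the condition; the normalized score in [0, 1] scales each reaction's
default bound magnitude.  Exchange reactions are reset to availability
magnitude 1 (import-positive reading of the -1/1 convention).

Free amino-acid measurements (umol/gDW) replace the 20 amino-acid drain
coefficients of the biomass composition, after which the composition is
rescaled back to 1 g/mmol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .curation import BiomassComposition, rescale_biomass
from .model import GPRExpr, MetabolicModel

__all__ = [
    "AMINO_ACIDS",
    "ExpressionTable",
    "AminoAcidTable",
    "summarize_expression",
    "score_gpr",
    "apply_eflux",
    "incorporate_amino_acids",
    "NO_CONSTRAINT",
]

#: The 20 proteinogenic amino acids (three-letter names used throughout).
AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: Sentinel returned for an empty GPR: the reaction stays unconstrained.
NO_CONSTRAINT = object()


@dataclass
class ExpressionTable:
    """Gene x replicate FPKM values for one condition."""

    condition: str
    rows: dict[str, tuple[float, ...]]  # gene_id -> replicate FPKM values

    def __post_init__(self):
        counts = {len(v) for v in self.rows.values()}
        if len(counts) > 1:
            raise ValueError(f"unequal replicate counts in condition "
                             f"{self.condition!r}: {sorted(counts)}")
        for gene, values in self.rows.items():
            if not values:
                raise ValueError(f"gene {gene}: no replicates")
            if any(v < 0 for v in values):
                raise ValueError(f"gene {gene}: negative FPKM")

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_frame(self):
        import pandas as pd
        n = self.n_replicates
        return pd.DataFrame.from_dict(
            self.rows, orient="index",
            columns=[f"rep{i + 1}" for i in range(n)]).rename_axis("gene_id")

    @classmethod
    def from_tsv(cls, path: str, condition: str) -> "ExpressionTable":
        import pandas as pd
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(condition,
                   {g: tuple(float(x) for x in row)
                    for g, row in frame.iterrows()})

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class AminoAcidTable:
    """Free amino-acid concentrations (umol per gDW) for one condition."""

    condition: str
    rows: dict[str, float]  # amino-acid name -> concentration

    def __post_init__(self):
        for name, conc in self.rows.items():
            if name not in AMINO_ACIDS:
                raise ValueError(f"unknown amino-acid name {name!r}")
            if conc < 0:
                raise ValueError(f"{name}: negative concentration")

    def total(self) -> float:
        return sum(self.rows.values())

    @classmethod
    def from_csv(cls, path: str, condition: str) -> "AminoAcidTable":
        import pandas as pd
        frame = pd.read_csv(path)
        return cls(condition, {str(r["name"]): float(r["umol_per_g"])
                               for _, r in frame.iterrows()})

    def to_csv(self, path: str) -> None:
        import pandas as pd
        pd.DataFrame({"name": list(self.rows), "umol_per_g":
                      list(self.rows.values())}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def summarize_expression(table: ExpressionTable) -> dict[str, float]:
    """Per-gene activity score log2(mean(FPKM) + 1)."""
    return {gene: math.log2(sum(values) / len(values) + 1.0)
            for gene, values in table.rows.items()}


def score_gpr(expr: GPRExpr | None, scores: dict[str, float]):
    """Evaluate a GPR tree: OR = sum, AND = min, leaf = gene score.

    Genes missing from the table count as unexpressed (score 0) with a
    warning.  An empty expression returns the NO_CONSTRAINT sentinel.
    """
    if expr is None:
        return NO_CONSTRAINT
    if expr.op == "gene":
        if expr.gene not in scores:
            warnings.warn(f"gene {expr.gene} missing from expression table; "
                          "treated as unexpressed", stacklevel=2)
            return 0.0
        return scores[expr.gene]
    child_values = [score_gpr(c, scores) for c in expr.children]
    if expr.op == "or":
        return float(sum(child_values))
    return float(min(child_values))


# ---------------------------------------------------------------------------
# Bound application
# ---------------------------------------------------------------------------

@dataclass
class EFluxResult:
    model: MetabolicModel
    reaction_scores: dict[str, float] = field(default_factory=dict)
    normalized: dict[str, float] = field(default_factory=dict)
    #: reaction id -> (old bounds, new bounds)
    bound_changes: dict[str, tuple[tuple[float, float], tuple[float, float]]] = (
        field(default_factory=dict))


def apply_eflux(model: MetabolicModel, table: ExpressionTable,
                ) -> EFluxResult:
    """Return a context-specific copy of the model.

    Per reaction with a GPR: normalized score s scales the default bound
    magnitudes (upper -> s*|ub|; lower -> -s*|lb| if reversible, else 0).
    Reactions without a GPR are untouched.  Every exchange is reset to
    availability magnitude 1 (lower bound -1 only where the exchange was
    reversible to begin with: photons and nutrients cannot be excreted).
    """
    scores = summarize_expression(table)
    raw: dict[str, float] = {}
    for rxn in model.reactions:
        value = score_gpr(rxn.gpr, scores)
        if value is not NO_CONSTRAINT:
            raw[rxn.id] = float(value)
    if not raw:
        raise ValueError("model has no reactions with GPRs; nothing to scale")
    peak = max(raw.values())
    if peak <= 0:
        raise ValueError("all GPR scores are zero; normalization undefined")
    normalized = {rid: v / peak for rid, v in raw.items()}

    context = model.copy()
    changes = {}
    for rxn in context.reactions:
        old = (rxn.lower_bound, rxn.upper_bound)
        if rxn.kind == "exchange":
            rxn.upper_bound = 1.0
            rxn.lower_bound = -1.0 if old[0] < 0 else 0.0
        elif rxn.id in normalized:
            s = normalized[rxn.id]
            rxn.upper_bound = s * abs(old[1])
            rxn.lower_bound = -s * abs(old[0]) if old[0] < 0 else 0.0
        if (rxn.lower_bound, rxn.upper_bound) != old:
            changes[rxn.id] = (old, (rxn.lower_bound, rxn.upper_bound))
    return EFluxResult(context, raw, normalized, changes)


def incorporate_amino_acids(composition: BiomassComposition,
                            table: AminoAcidTable) -> BiomassComposition:
    """Replace the 20 amino-acid coefficients with measured free
    concentrations (umol/gDW -> mmol/gDW) and rescale to 1 g/mmol."""
    by_name = {c.name for c in composition}
    missing = [aa for aa in AMINO_ACIDS if aa not in by_name]
    if missing:
        raise ValueError(f"composition lacks amino-acid drains: {missing}")
    updated = composition
    for name, conc in table.rows.items():
        updated = updated.with_coefficient(name, conc / 1000.0)
    return rescale_biomass(updated)
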