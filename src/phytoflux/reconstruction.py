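"""Draft model assembly: reaction tables -> compartmentalized scaffold.

The assembly pipeline mirrors how plant genome-scale models are built:

1. :func:`assemble_draft` parses a reaction table plus a GPR table into a
   single-compartment (cytosolic) draft;
2. :func:`assign_compartments` relocates gene-associated reactions using a
   three-tier evidence cascade (curated database > related-species model >
   localization predictor), cytosol remaining the default;
3. :func:`add_transport_reactions` wires every non-cytosolic compartment
   to the cytosol hub (suffixes _pc/_mc/_xc/_vc), optionally with an ATP
   cost per transported unit;
4. :func:`add_boundary` attaches the exchange reactions (``_Cyto_tx``),
   biomass drains (``_biomass``) and the biomass assembly reaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .model import (
    DEFAULT_UPPER,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

__all__ = [
    "LocalizationEvidence",
    "BoundarySpec",
    "assemble_draft",
    "assign_compartments",
    "add_transport_reactions",
    "add_boundary",
]

logger = logging.getLogger(__name__)

EVIDENCE_SOURCES = ("uniprot", "related_gem", "predictor")
_SOURCE_PRIORITY = {src: i for i, src in enumerate(EVIDENCE_SOURCES)}
_TRANSPORT_SUFFIX = {"p": "pc", "m": "mc", "x": "xc", "v": "vc"}


@dataclass(frozen=True)
class LocalizationEvidence:
    gene_id: str
    source: str  # uniprot | related_gem | predictor
    compartment: str  # c | m | p | x | v

    def __post_init__(self):
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.compartment not in ("c", "m", "p", "x", "v"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @staticmethod
    def read_tsv(path: str) -> list["LocalizationEvidence"]:
        import pandas as pd
        frame = pd.read_csv(path, sep="\t")
        return [LocalizationEvidence(str(r["gene_id"]), str(r["source"]),
                                     str(r["compartment"]))
                for _, r in frame.iterrows()]


# ---------------------------------------------------------------------------
# Draft assembly
# ---------------------------------------------------------------------------

def _parse_stoichiometry(text: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = (text or "").strip()
    if not text:
        return stoich
    for item in text.split(";"):
        name, sep, coeff = item.partition(":")
        if not sep or not name.strip():
            raise ValueError(f"malformed stoichiometry item {item!r}")
        stoich[name.strip()] = float(coeff)
    return stoich


def assemble_draft(reaction_table, gpr_table=None) -> MetabolicModel:
    """Build a cytosolic draft from tables.

    ``reaction_table`` is a TSV path or DataFrame with columns
    ``id, stoichiometry, reversible[, name, subsystem]`` where
    stoichiometry uses species base names (``species:coeff;...``,
    negative = consumed).  ``gpr_table`` has ``reaction_id, gpr``.
    Every species is placed in the cytosol; metabolites are created on
    the fly without formulas (curation adds them later).
    """
    import pandas as pd

    if isinstance(reaction_table, str):
        reaction_table = pd.read_csv(reaction_table, sep="\t")
    gprs: dict[str, str] = {}
    if gpr_table is not None:
        if isinstance(gpr_table, str):
            gpr_table = pd.read_csv(gpr_table, sep="\t")
        gprs = {str(r["reaction_id"]): str(r["gpr"])
                for _, r in gpr_table.iterrows()}

    model = MetabolicModel(name="draft")
    if reaction_table.empty:
        warnings.warn("empty reaction table: returning an empty draft model",
                      stacklevel=2)
        return model
    for row_number, row in enumerate(reaction_table.itertuples(index=False),
                                     start=2):
        try:
            stoich = _parse_stoichiometry(row.stoichiometry)
        except ValueError as exc:
            raise ValueError(
                f"reaction table row {row_number} ({row.id}): {exc}") from exc
        full = {}
        for species, coeff in stoich.items():
            met_id = f"{species}_c"
            if not model.has_metabolite(met_id):
                model.add_metabolite(Metabolite(met_id, name=species,
                                                compartment="c"))
            full[met_id] = coeff
        reversible = bool(getattr(row, "reversible", False))
        model.add_reaction(Reaction(
            id=str(row.id), stoichiometry=full,
            lower_bound=-DEFAULT_UPPER if reversible else 0.0,
            upper_bound=DEFAULT_UPPER,
            gpr=parse_gpr(gprs.get(str(row.id), "")),
            subsystem=str(getattr(row, "subsystem", "") or ""),
            name=str(getattr(row, "name", "") or "")))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Compartment assignment
# ---------------------------------------------------------------------------

def _winning_compartments(genes: set[str],
                          by_gene: dict[str, list[LocalizationEvidence]],
                          ) -> tuple[list[str], str | None]:
    """Compartments at the highest evidence tier present for any of the
    reaction's genes.  Within a tier, the first record in file order wins
    per gene (D5); distinct winning genes may still name several
    compartments, in which case the reaction is duplicated."""
    for source in EVIDENCE_SOURCES:
        winners: list[str] = []
        for gene in sorted(genes):
            records = [e for e in by_gene.get(gene, []) if e.source == source]
            if not records:
                continue
            chosen = records[0]
            if len({e.compartment for e in records}) > 1:
                logger.warning(
                    "conflicting %s evidence for gene %s: %s; keeping first "
                    "record (%s)", source, gene,
                    sorted({e.compartment for e in records}), chosen.compartment)
            if chosen.compartment not in winners:
                winners.append(chosen.compartment)
        if winners:
            return winners, source
    return [], None


def _relocate(rxn: Reaction, compartment: str, model: MetabolicModel,
              suffix: str = "") -> Reaction:
    stoich = {}
    for met_id, coeff in rxn.stoichiometry.items():
        base = met_id.rsplit("_", 1)[0]
        new_id = f"{base}_{compartment}"
        if not model.has_metabolite(new_id):
            old = model.metabolite(met_id)
            model.add_metabolite(Metabolite(
                new_id, name=old.name, formula=old.formula,
                charge=old.charge, compartment=compartment))
        stoich[new_id] = coeff
    return Reaction(id=rxn.id + suffix, stoichiometry=stoich,
                    lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                    gpr=rxn.gpr, kind=rxn.kind, subsystem=rxn.subsystem,
                    name=rxn.name)


def assign_compartments(model: MetabolicModel,
                        evidence: list[LocalizationEvidence],
                        ):
    """Relocate gene-associated reactions by the evidence cascade.

    Returns ``(new_model, provenance)`` where provenance maps reaction id
    -> deciding evidence tier (``"default"`` for cytosol).  Deterministic
    and order-independent apart from the documented first-record tie rule.
    """
    by_gene: dict[str, list[LocalizationEvidence]] = {}
    for record in evidence:
        by_gene.setdefault(record.gene_id, []).append(record)

    out = MetabolicModel(name=model.name, compartments={"c"},
                         objective_reaction=model.objective_reaction,
                         pathway_tags=dict(model.pathway_tags))
    for met in model.metabolites:
        out.add_metabolite(Metabolite(met.id, name=met.name,
                                      formula=met.formula, charge=met.charge,
                                      compartment=met.compartment))
    provenance: dict[str, str] = {}
    for rxn in model.reactions:
        genes = rxn.gpr.genes() if rxn.gpr is not None else set()
        compartments, source = _winning_compartments(genes, by_gene)
        if not compartments or compartments == ["c"]:
            out.add_reaction(_relocate(rxn, "c", out))
            provenance[rxn.id] = source or "default"
            continue
        # multi-compartment evidence at the winning tier: duplicate
        many = len(compartments) > 1
        for comp in compartments:
            suffix = f"_{comp}" if many else ""
            new = _relocate(rxn, comp, out, suffix=suffix)
            out.add_reaction(new)
            provenance[new.id] = source
    out.validate()
    return out, provenance


# ---------------------------------------------------------------------------
# Transport reactions
# ---------------------------------------------------------------------------

def add_transport_reactions(model: MetabolicModel, transporter_table,
                            ) -> MetabolicModel:
    """Add cytosol-hub transporters from a table with columns
    ``species, compartment[, atp_cost, reversible]``.

    A row asking for transport between two non-cytosolic compartments is
    rejected (every inter-compartment exchange goes through the cytosol).
    An ATP cost makes the transporter irreversible and hydrolyzes that
    many ATP per transported unit.
    """
    import pandas as pd

    if isinstance(transporter_table, str):
        transporter_table = pd.read_csv(transporter_table, sep="\t")
    out = model.copy()
    for _, row in transporter_table.iterrows():
        comp = str(row["compartment"])
        if comp == "c" or comp not in _TRANSPORT_SUFFIX:
            raise ModelValidationError(
                f"transport for {row['species']}: target compartment must be "
                f"one of {sorted(_TRANSPORT_SUFFIX)} (all transport passes "
                "through the cytosol)")
        species = str(row["species"])
        atp_cost = float(row.get("atp_cost", 0.0) or 0.0)
        reversible = bool(row.get("reversible", True)) and atp_cost == 0.0
        rid = f"{species.upper()}_{_TRANSPORT_SUFFIX[comp]}"
        for met_id, template in ((f"{species}_{comp}", f"{species}_c"),
                                 (f"{species}_c", None)):
            if not out.has_metabolite(met_id):
                base = out.metabolite(template) if template and \
                    out.has_metabolite(template) else None
                out.add_metabolite(Metabolite(
                    met_id, name=base.name if base else species,
                    formula=base.formula if base else None,
                    charge=base.charge if base else None,
                    compartment=met_id.rsplit("_", 1)[1]))
        stoich = {f"{species}_{comp}": -1.0, f"{species}_c": 1.0}
        if atp_cost > 0:
            for base, coeff in (("atp", -atp_cost), ("h2o", -atp_cost),
                                ("adp", atp_cost), ("pi", atp_cost),
                                ("h", atp_cost)):
                met_id = f"{base}_c"
                if not out.has_metabolite(met_id):
                    out.add_metabolite(Metabolite(met_id, name=base,
                                                  compartment="c"))
                stoich[met_id] = stoich.get(met_id, 0.0) + coeff
        out.add_reaction(Reaction(
            id=rid, stoichiometry=stoich,
            lower_bound=-DEFAULT_UPPER if reversible else 0.0,
            upper_bound=DEFAULT_UPPER,
            kind="transport", subsystem="transport"))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Boundary structure
# ---------------------------------------------------------------------------

@dataclass
class BoundarySpec:
    """Exchanges and biomass drains to attach to a scaffold.

    ``exchanges``: (species, direction, bound) with direction in
    {import, both}; ``biomass_components``: (metabolite id, coefficient in
    mmol/gDW).
    """

    exchanges: list[tuple[str, str, float]] = field(default_factory=list)
    biomass_components: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for species, direction, bound in self.exchanges:
            if species in seen:
                raise ModelValidationError(
                    f"duplicate exchange species {species!r}")
            seen.add(species)
            if direction not in ("import", "both"):
                raise ModelValidationError(
                    f"exchange {species}: direction must be import|both")
            if bound < 0:
                raise ModelValidationError(f"exchange {species}: bound < 0")
        seen = set()
        for met_id, coeff in self.biomass_components:
            if met_id in seen:
                raise ModelValidationError(
                    f"duplicate biomass component {met_id!r}")
            seen.add(met_id)
            if coeff <= 0:
                raise ModelValidationError(
                    f"biomass component {met_id}: coefficient must be > 0")

    @staticmethod
    def from_yaml(path: str) -> "BoundarySpec":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return BoundarySpec(
            exchanges=[(e["species"], e.get("direction", "import"),
                        float(e.get("bound", DEFAULT_UPPER)))
                       for e in data.get("exchanges", [])],
            biomass_components=[(c["metabolite"], float(c["coefficient"]))
                                for c in data.get("biomass_components", [])])


def add_boundary(model: MetabolicModel, spec: BoundarySpec) -> MetabolicModel:
    """Attach exchanges, biomass drains and the biomass reaction.

    Raises if the model already carries boundary reactions (applying a
    spec twice must not silently duplicate the boundary).
    """
    if model.exchanges() or model.biomass_drains():
        raise ModelValidationError(
            "model already has boundary reactions; boundary construction "
            "is not repeatable")
    out = model.copy()
    for species, direction, bound in spec.exchanges:
        met_id = f"{species.lower()}_c"
        if not out.has_metabolite(met_id):
            out.add_metabolite(Metabolite(met_id, name=species,
                                          compartment="c"))
        out.add_reaction(Reaction(
            id=f"{species}_Cyto_tx", stoichiometry={met_id: 1.0},
            lower_bound=-bound if direction == "both" else 0.0,
            upper_bound=bound, kind="exchange", subsystem="exchange"))
    if spec.biomass_components:
        pools = []
        for met_id, coeff in spec.biomass_components:
            if not out.has_metabolite(met_id):
                raise ModelValidationError(
                    f"biomass component {met_id} not in model")
            base = met_id.rsplit("_", 1)[0]
            pool = f"bm_{base}_c"
            out.add_metabolite(Metabolite(pool, name=f"biomass pool: {base}",
                                          compartment="c"))
            out.add_reaction(Reaction(
                id=f"{base}_biomass",
                stoichiometry={met_id: -coeff, pool: 1.0},
                lower_bound=0.0, upper_bound=DEFAULT_UPPER,
                kind="biomass_drain", subsystem="biomass"))
            pools.append(pool)
        out.add_reaction(Reaction(
            id="Biomass", stoichiometry={pool: -1.0 for pool in pools},
            lower_bound=0.0, upper_bound=DEFAULT_UPPER,
            kind="biomass", subsystem="biomass"))
        out.objective_reaction = "Biomass"
    out.validate()
    return out
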