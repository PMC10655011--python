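"""Readers and writers for the formats stoichiometric models travel in.

Three dialects:

* **json** — the native format.  Fields mirror the domain types one-to-one
  and the write -> read round trip is the identity (bounds and
  stoichiometric coefficients are serialized as exact repr floats, GPRs as
  rule strings re-parsed to an identical tree).  Exchange reactions are
  import-positive (D1) and the file says so in its header.
* **sbml_fbc** — SBML Level 3 + FBC for interchange with other tools,
  delegated to cobrapy.  Sign conventions are preserved verbatim: an
  import-positive exchange is simply a one-metabolite reaction.
* **tsv_tables** — a human-editable triple ``metabolites.tsv`` /
  ``reactions.tsv`` / ``gprs.tsv`` in a directory.
"""

from __future__ import annotations

import json
import os
from typing import Any

from .model import (
    GPRExpr,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

__all__ = ["read_model", "write_model", "FormatError"]

_JSON_HEADER = (
    "phytoflux model JSON dialect v1; exchange reactions are import-positive "
    "(positive flux = uptake)"
)


class FormatError(ValueError):
    """A file failed to parse in the named dialect."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict[str, Any]:
    return {
        "format": _JSON_HEADER,
        "name": model.name,
        "objective_reaction": model.objective_reaction,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gpr": r.gpr_string(),
                "kind": r.kind,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "pathway_tags": model.pathway_tags,
    }


def _model_from_dict(data: dict[str, Any]) -> MetabolicModel:
    model = MetabolicModel(
        name=data.get("name", ""),
        objective_reaction=data.get("objective_reaction"),
        compartments=set(data.get("compartments", [])),
        pathway_tags=dict(data.get("pathway_tags", {})),
    )
    for entry in data.get("metabolites", []):
        model.add_metabolite(Metabolite(
            id=entry["id"],
            name=entry.get("name", ""),
            formula=entry.get("formula"),
            charge=entry.get("charge"),
            compartment=entry.get("compartment", "c"),
        ))
    for entry in data.get("reactions", []):
        model.add_reaction(Reaction(
            id=entry["id"],
            name=entry.get("name", ""),
            stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
            lower_bound=float(entry["lower_bound"]),
            upper_bound=float(entry["upper_bound"]),
            gpr=parse_gpr(entry.get("gpr", "")),
            kind=entry.get("kind", "biochemical"),
            subsystem=entry.get("subsystem", ""),
        ))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# TSV triple
# ---------------------------------------------------------------------------

def _write_tsv_tables(model: MetabolicModel, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "metabolites.tsv"), "w") as fh:
        fh.write("id\tname\tformula\tcharge\tcompartment\n")
        for m in model.metabolites:
            # empty cell = unknown formula; "." = known massless species
            formula = "" if m.formula is None else (m.formula or ".")
            fh.write(f"{m.id}\t{m.name}\t{formula}"
                     f"\t{'' if m.charge is None else m.charge}\t{m.compartment}\n")
    with open(os.path.join(dirpath, "reactions.tsv"), "w") as fh:
        fh.write("id\tname\tstoichiometry\tlower_bound\tupper_bound\tkind\tsubsystem\n")
        for r in model.reactions:
            stoich = ";".join(f"{met}:{coeff!r}" for met, coeff in r.stoichiometry.items())
            fh.write(f"{r.id}\t{r.name}\t{stoich}\t{r.lower_bound!r}\t{r.upper_bound!r}"
                     f"\t{r.kind}\t{r.subsystem}\n")
    with open(os.path.join(dirpath, "gprs.tsv"), "w") as fh:
        fh.write("reaction_id\tgpr\n")
        for r in model.reactions:
            if r.gpr is not None:
                fh.write(f"{r.id}\t{r.gpr_string()}\n")


def _read_tsv_tables(dirpath: str) -> MetabolicModel:
    import csv

    def rows(name):
        path = os.path.join(dirpath, name)
        if not os.path.exists(path):
            raise FormatError(f"missing table {name} in {dirpath}")
        with open(path) as fh:
            yield from csv.DictReader(fh, delimiter="\t")

    model = MetabolicModel()
    for lineno, row in enumerate(rows("metabolites.tsv"), start=2):
        try:
            model.add_metabolite(Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                formula=(None if not row.get("formula")
                         else "" if row["formula"] == "." else row["formula"]),
                charge=int(row["charge"]) if row.get("charge") else None,
                compartment=row.get("compartment", "c"),
            ))
        except (ModelValidationError, ValueError) as exc:
            raise FormatError(f"metabolites.tsv line {lineno}: {exc}") from exc

    gprs: dict[str, GPRExpr] = {}
    for lineno, row in enumerate(rows("gprs.tsv"), start=2):
        try:
            expr = parse_gpr(row["gpr"])
        except ModelValidationError as exc:
            raise FormatError(f"gprs.tsv line {lineno}: {exc}") from exc
        if expr is not None:
            gprs[row["reaction_id"]] = expr

    for lineno, row in enumerate(rows("reactions.tsv"), start=2):
        try:
            stoich: dict[str, float] = {}
            text = row["stoichiometry"].strip()
            if text:
                for item in text.split(";"):
                    met, _, coeff = item.partition(":")
                    if not _ or not met:
                        raise FormatError(f"malformed stoichiometry item {item!r}")
                    stoich[met.strip()] = float(coeff)
            model.add_reaction(Reaction(
                id=row["id"],
                name=row.get("name", ""),
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                gpr=gprs.get(row["id"]),
                kind=row.get("kind") or "biochemical",
                subsystem=row.get("subsystem", ""),
            ))
        except FormatError:
            raise
        except (ModelValidationError, ValueError, KeyError) as exc:
            raise FormatError(f"reactions.tsv line {lineno}: {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC (via cobrapy)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML interchange and as an
    independent solver cross-check in the test suite)."""
    import cobra

    cm = cobra.Model(model.name or "phytoflux_model")
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name or m.id, compartment=m.compartment,
            formula=m.formula, charge=m.charge)
        mets[m.id] = cmet
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name or r.id,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        cr.subsystem = r.subsystem
        reactions.append(cr)
    cm.add_reactions(reactions)
    # gene rules must be set after the reactions belong to the model
    for r in model.reactions:
        if r.gpr is not None:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = r.gpr_string()
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


def _from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(name=cm.name or "")
    for m in cm.metabolites:
        compartment = m.compartment if m.compartment in ("c", "m", "p", "x", "v") else "c"
        model.add_metabolite(Metabolite(
            id=m.id, name=m.name or "", formula=m.formula or None,
            charge=int(m.charge) if m.charge is not None else None,
            compartment=compartment))
    for r in cm.reactions:
        rid = r.id
        if rid.endswith("_Cyto_tx"):
            kind = "exchange"
        elif rid.endswith("_biomass"):
            kind = "biomass_drain"
        elif rid == "Biomass" or "biomass" in (r.name or "").lower():
            kind = "biomass"
        else:
            comps = {m.compartment for m in r.metabolites}
            kind = "transport" if len(comps) == 2 and "c" in comps else "biochemical"
        model.add_reaction(Reaction(
            id=rid, name=r.name or "",
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=float(r.lower_bound), upper_bound=float(r.upper_bound),
            gpr=parse_gpr(r.gene_reaction_rule or ""),
            kind=kind, subsystem=r.subsystem or ""))
    objective = [r.id for r in cm.reactions
                 if r.objective_coefficient not in (0, None)]
    if objective:
        model.objective_reaction = objective[0]
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, path: str, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1)
            fh.write("\n")
    elif format == "sbml_fbc":
        import cobra
        cobra.io.write_sbml_model(to_cobra(model), path)
    elif format == "tsv_tables":
        _write_tsv_tables(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path: str, format: str = "json") -> MetabolicModel:
    if format == "json":
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path}")
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        try:
            return _model_from_dict(data)
        except (KeyError, ModelValidationError, ValueError) as exc:
            if isinstance(exc, ModelValidationError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    if format == "sbml_fbc":
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path}")
        import cobra
        return _from_cobra(cobra.io.read_sbml_model(path))
    if format == "tsv_tables":
        return _read_tsv_tables(path)
    raise ValueError(f"unknown model format {format!r}")
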