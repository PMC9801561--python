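"""Model I/O: SBML Level 3 + FBC (via libsbml) and BiGG-style JSON.

Both dialects round-trip every field of :class:`~gemforge.core.Model`.
Subsystem, provenance and the free-form annotation maps travel in SBML
reaction/species notes (``<p>KEY: value</p>`` entries, the convention
used across the constraint-based modelling ecosystem); JSON carries
them natively.  Bounds omitted by a file default to ±1000
mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

import json
import math
from fractions import Fraction
from pathlib import Path

import libsbml

from .core import (
    DEFAULT_LOWER_BOUND,
    DEFAULT_UPPER_BOUND,
    Gene,
    Metabolite,
    Model,
    ModelIntegrityError,
    Reaction,
    format_formula,
    parse_formula,
)
from .gpr import EMPTY_RULE, GeneRule, parse_gpr


class ParseError(ValueError):
    """A file could not be parsed under the named standard."""


def read_model(path: str | Path, format: str | None = None) -> Model:
    """Read a model from SBML (L3+FBC) or BiGG-style JSON.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred
    from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: Model, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        _write_json(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _num(value: Fraction) -> float | int:
    f = float(value)
    return int(f) if f.is_integer() else f


def _write_json(model: Model, path: Path) -> None:
    doc = {
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": format_formula(m.formula)} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                "annotation": m.annotations,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {m: _num(c) for m, c in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "annotation": r.annotations,
                "notes": {"origin": r.provenance},
                "objective_coefficient": model.objective.get(r.id, 0),
            }
            for r in model.reactions.values()
        ],
        "genes": [
            {"id": g.id, "name": g.name, "notes": {"locus_tag": g.locus_tag}}
            for g in model.genes.values()
        ],
        "version": "1",
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def _read_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "reactions" not in doc or "metabolites" not in doc:
        raise ParseError(f"{path}: missing 'metabolites'/'reactions' arrays")
    model = Model(id=doc.get("id", path.stem))
    model.compartments = dict(doc.get("compartments", {}))
    for g in doc.get("genes", []):
        model.genes[g["id"]] = Gene(
            id=g["id"],
            name=g.get("name", ""),
            locus_tag=(g.get("notes") or {}).get("locus_tag", ""),
        )
    for m in doc["metabolites"]:
        try:
            formula = parse_formula(m["formula"]) if m.get("formula") else None
        except ValueError as exc:
            raise ParseError(f"{path}: metabolite {m.get('id')}: {exc}") from exc
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=formula,
                charge=m.get("charge"),
                annotations=m.get("annotation", {}) or {},
            )
        )
    for r in doc["reactions"]:
        rule = parse_gpr(r.get("gene_reaction_rule", "") or "")
        rxn = Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={m: c for m, c in r["metabolites"].items()},
            lower_bound=float(r.get("lower_bound", DEFAULT_LOWER_BOUND)),
            upper_bound=float(r.get("upper_bound", DEFAULT_UPPER_BOUND)),
            gpr=rule,
            subsystem=r.get("subsystem", "") or "",
            annotations=r.get("annotation", {}) or {},
            provenance=(r.get("notes") or {}).get("origin", "manual"),
        )
        model.add_reaction(rxn)
        coeff = r.get("objective_coefficient", 0)
        if coeff:
            model.objective[r["id"]] = float(coeff)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

_SBML_PREFIX = {"species": "M_", "reaction": "R_", "gene": "G_"}


def _sid(kind: str, raw: str) -> str:
    """SBML id: prefixed, with characters outside [A-Za-z0-9_] escaped."""
    safe = "".join(c if c.isalnum() or c == "_" else f"__{ord(c)}__" for c in raw)
    return _SBML_PREFIX[kind] + safe


def _unsid(kind: str, sid: str) -> str:
    prefix = _SBML_PREFIX[kind]
    raw = sid[len(prefix):] if sid.startswith(prefix) else sid
    out, i = [], 0
    while i < len(raw):
        if raw.startswith("__", i):
            end = raw.find("__", i + 2)
            if end > i + 2 and raw[i + 2:end].isdigit():
                out.append(chr(int(raw[i + 2:end])))
                i = end + 2
                continue
        out.append(raw[i])
        i += 1
    return "".join(out)


def _notes_xhtml(entries: dict[str, str]) -> str:
    ps = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items() if v)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{ps}</body>'


def _parse_notes(node) -> dict[str, str]:
    entries: dict[str, str] = {}
    if node is None or not node.isSetNotes():
        return entries
    text = node.getNotesString()
    # each <p>KEY: value</p> entry
    import re

    for m in re.finditer(r"<p>\s*([^:<]+):\s*(.*?)</p>", text, re.S):
        entries[m.group(1).strip()] = m.group(2).strip()
    return entries


def _write_sbml(model: Model, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid("species", met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(met.charge)
        notes = {}
        if met.annotations:
            notes["ANNOTATIONS"] = json.dumps(met.annotations, sort_keys=True)
        if notes:
            sp.setNotes(_notes_xhtml(notes))

    for gene in model.genes.values():
        gp = mplug.createGeneProduct()
        gp.setId(_sid("gene", gene.id))
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)
        if gene.locus_tag:
            gp.setMetaId(_sid("gene", gene.id))
            gp.setNotes(_notes_xhtml({"LOCUS_TAG": gene.locus_tag}))

    # one shared parameter per distinct bound value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def attach_association(node, container) -> None:
        if isinstance(node, str):
            ref = container.createGeneProductRef()
            ref.setGeneProduct(_sid("gene", node))
            return
        op, children = node
        sub = container.createAnd() if op == "and" else container.createOr()
        for child in children:
            attach_association(child, sub)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid("reaction", rxn.id))
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for mid, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(float(-coeff))
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_sid("species", mid))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            root = rxn.gpr.root
            if isinstance(root, str):
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(_sid("gene", root))
            else:
                op, children = root
                top = gpa.createAnd() if op == "and" else gpa.createOr()
                for child in children:
                    attach_association(child, top)
        notes = {"SUBSYSTEM": rxn.subsystem, "ORIGIN": rxn.provenance}
        if rxn.annotations:
            notes["ANNOTATIONS"] = json.dumps(rxn.annotations, sort_keys=True)
        sr.setNotes(_notes_xhtml(notes))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    for rid, weight in model.objective.items():
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("reaction", rid))
        fo.setCoefficient(float(weight))

    libsbml.writeSBMLToFile(doc, str(path))


def _walk_association(assoc, gene_label: dict[str, str]):
    if isinstance(assoc, libsbml.GeneProductRef):
        return gene_label[assoc.getGeneProduct()]
    if isinstance(assoc, libsbml.FbcAnd):
        op = "and"
    elif isinstance(assoc, libsbml.FbcOr):
        op = "or"
    else:  # pragma: no cover - no other association classes in FBC v2
        raise ParseError(f"unsupported GPR association node {type(assoc).__name__}")
    children = tuple(
        _walk_association(assoc.getAssociation(i), gene_label)
        for i in range(assoc.getNumAssociations())
    )
    return (op, children)


def _read_sbml(path: Path) -> Model:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise ParseError(f"{path}: no <model> element")
    model = Model(id=sm.getId() or path.stem)
    mplug = sm.getPlugin("fbc")

    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    gene_label: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _unsid("gene", gp.getId())
            gene_label[gp.getId()] = label
            notes = _parse_notes(gp)
            model.genes[label] = Gene(
                id=label, name=gp.getName() or "", locus_tag=notes.get("LOCUS_TAG", "")
            )

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        notes = _parse_notes(sp)
        annotations = json.loads(notes["ANNOTATIONS"]) if "ANNOTATIONS" in notes else {}
        model.add_metabolite(
            Metabolite(
                id=_unsid("species", sp.getId()),
                name=sp.getName() or "",
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotations=annotations,
            )
        )

    param_value = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _unsid("reaction", sr.getId())
        stoich: dict[str, Fraction] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _unsid("species", ref.getSpecies())
            stoich[mid] = stoich.get(mid, Fraction(0)) - Fraction(repr(ref.getStoichiometry()))
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _unsid("species", ref.getSpecies())
            stoich[mid] = stoich.get(mid, Fraction(0)) + Fraction(repr(ref.getStoichiometry()))
        rplug = sr.getPlugin("fbc")
        lb, ub = DEFAULT_LOWER_BOUND, DEFAULT_UPPER_BOUND
        rule: GeneRule = EMPTY_RULE
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_value[rplug.getLowerFluxBound()]
            if rplug.isSetUpperFluxBound():
                ub = param_value[rplug.getUpperFluxBound()]
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.isSetAssociation():
                rule = GeneRule(_walk_association(gpa.getAssociation(), gene_label))
        notes = _parse_notes(sr)
        annotations = json.loads(notes["ANNOTATIONS"]) if "ANNOTATIONS" in notes else {}
        model.add_reaction(
            Reaction(
                id=rid,
                name=sr.getName() or "",
                stoichiometry={m: c for m, c in stoich.items() if c != 0},
                lower_bound=lb,
                upper_bound=ub,
                gpr=rule,
                subsystem=notes.get("SUBSYSTEM", ""),
                annotations=annotations,
                provenance=notes.get("ORIGIN", "manual"),
            )
        )

    if mplug is not None:
        obj = mplug.getActiveObjective() or (
            mplug.getObjective(0) if mplug.getNumObjectives() else None
        )
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(j)
                model.objective[_unsid("reaction", fo.getReaction())] = fo.getCoefficient()
    model.validate()
    return model
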