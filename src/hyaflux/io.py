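"""Model input/output.

Two dialects are supported:

* the native tabular format — a TSV reaction table (columns: id, name,
  equation, lb, ub, gpr, kind, subsystem) plus a JSON sidecar (same stem,
  ``.json``) holding metabolites, genes, the objective and model metadata;
* an SBML Level 3 (fbc version 2) subset — species with formula/charge,
  reactions with flux-bound parameters and gene-product associations, and a
  single maximization objective.  Written files are readable by standard
  COBRA tooling.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml

from .gpr import parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = ["read_model", "write_model", "parse_equation"]

TSV_COLUMNS = ["id", "name", "equation", "lb", "ub", "gpr", "kind", "subsystem"]

_ARROWS = ("<=>", "-->", "<--")


def parse_equation(text: str) -> tuple[dict, bool]:
    """Parse ``"2 A + B --> C"`` into (stoichiometry dict, reversible flag)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelValidationError(f"no reaction arrow in equation {text!r}")
    left, right = text.split(arrow)
    if arrow == "<--":
        left, right = right, left
    stoich: dict = {}

    def add(side: str, sign: int):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^((?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s+(\S+)$", term)
            if m:
                coef, met = float(m.group(1)), m.group(2)
            else:
                coef, met = 1.0, term
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add(left, -1)
    add(right, +1)
    return {m: c for m, c in stoich.items() if c != 0}, arrow == "<=>"


# -- native TSV + JSON -------------------------------------------------------


def _json_sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = ["\t".join(TSV_COLUMNS)]
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    r.equation(),
                    repr(r.lower_bound),
                    repr(r.upper_bound),
                    r.gpr.to_string(),
                    r.kind,
                    r.subsystem,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "id": model.id,
        "objective_reaction": model.objective_reaction,
        "genes": list(model.genes),
        "genome_gene_count": model.genome_gene_count,
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
    }
    _json_sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")


def _read_tsv(path: Path) -> MetabolicModel:
    meta = json.loads(_json_sidecar(path).read_text())
    metabolites = [Metabolite(**m) for m in meta["metabolites"]]
    reactions = []
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    if header != TSV_COLUMNS:
        raise ModelValidationError(f"unexpected TSV header {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        rid, name, equation, lb, ub, gpr, kind, subsystem = line.split("\t")
        stoich, _ = parse_equation(equation)
        reactions.append(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(gpr),
                kind=kind,
                subsystem=subsystem,
            )
        )
    model = MetabolicModel(
        id=meta["id"],
        metabolites=metabolites,
        reactions=reactions,
        genes=meta["genes"],
        objective_reaction=meta["objective_reaction"],
        genome_gene_count=meta.get("genome_gene_count"),
    )
    model.validate()
    return model


# -- SBML L3 + fbc v2 subset -------------------------------------------------

_NOTES = (
    '<body xmlns="http://www.w3.org/1999/xhtml">{}</body>'
)

# SBML SIds may not start with a digit; the conventional M_/R_/G_ prefixes
# keep metabolite/reaction/gene ids valid and are stripped on read.


def _sid(prefix: str, raw: str) -> str:
    return f"{prefix}{raw}"


def _strip_sid(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _sbml_check(status, what: str) -> None:
    if status not in (None, libsbml.LIBSBML_OPERATION_SUCCESS):
        raise RuntimeError(f"libsbml error while {what}: status {status}")


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    if model.genome_gene_count is not None:
        sm.setNotes(_NOTES.format(f"<p>genome_gene_count: {model.genome_gene_count}</p>"))

    for comp_id in ("c", "e"):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", gene))
        gp.setLabel(gene)

    def bound_param(value: float, pid: str) -> str:
        par = sm.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(_sid("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        sr.setNotes(
            _NOTES.format(
                f"<p>kind: {rxn.kind}</p><p>subsystem: {rxn.subsystem}</p>"
            )
        )
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, f"R_{rxn.id}__lb"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, f"R_{rxn.id}__ub"))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            # libsbml resolves the infix against gene-product *labels*
            _sbml_check(gpa.setAssociation(rxn.gpr.to_string()),
                        f"setting GPR of {rxn.id}")

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    if model.objective_reaction:
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective_reaction))
        fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, str(path)):
        raise RuntimeError(f"could not write SBML to {path}")


def _association_to_infix(assoc) -> str:
    if assoc is None:
        return ""
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return assoc.getGeneProduct()
    children = [
        _association_to_infix(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    if code == libsbml.SBML_FBC_AND:
        return " and ".join(f"({c})" if " or " in c else c for c in children)
    if code == libsbml.SBML_FBC_OR:
        return " or ".join(children)
    raise ModelValidationError(f"unsupported GPR association node {code}")


_NOTE_KV = re.compile(r"<p>\s*([^:<]+):\s*([^<]*)</p>")


def _parse_notes(element) -> dict:
    if not element.isSetNotes():
        return {}
    text = libsbml.XMLNode.convertXMLNodeToString(element.getNotes())
    return {k.strip(): v.strip() for k, v in _NOTE_KV.findall(text)}


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelValidationError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()}"
        )
    sm = doc.getModel()
    mplug = sm.getPlugin("fbc")

    gp_label = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gp_label[gp.getId()] = gp.getLabel() or gp.getId()

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        metabolites.append(
            Metabolite(
                id=_strip_sid("M_", sp.getId()),
                name=sp.getName(),
                formula=(
                    splug.getChemicalFormula()
                    if splug is not None and splug.isSetChemicalFormula()
                    else None
                ),
                charge=splug.getCharge() if splug is not None and splug.isSetCharge() else 0,
                compartment=sp.getCompartment(),
            )
        )

    reactions = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip_sid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip_sid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr_text = ""
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = sm.getParameter(rplug.getLowerFluxBound()).getValue()
            if rplug.isSetUpperFluxBound():
                ub = sm.getParameter(rplug.getUpperFluxBound()).getValue()
            if rplug.isSetGeneProductAssociation():
                raw = _association_to_infix(
                    rplug.getGeneProductAssociation().getAssociation()
                )
                gpr_text = re.sub(
                    r"\b[\w.\-]+\b",
                    lambda m: gp_label.get(m.group(0), m.group(0)),
                    raw,
                )
        notes = _parse_notes(sr)
        reactions.append(
            Reaction(
                id=_strip_sid("R_", sr.getId()),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr_text),
                kind=notes.get("kind", "internal"),
                subsystem=notes.get("subsystem", ""),
            )
        )

    objective = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId() or "obj") or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = _strip_sid("R_", obj.getFluxObjective(0).getReaction())

    genes = sorted(gp_label.values())
    notes = _parse_notes(sm)
    ggc = notes.get("genome_gene_count")
    model = MetabolicModel(
        id=sm.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction=objective,
        genome_gene_count=int(ggc) if ggc else None,
    )
    model.validate()
    return model


# -- public dispatch ---------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix in (".tsv", ".txt"):
        return "tsv"
    if path.suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}")


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a model from TSV+JSON (``format="tsv"``) or SBML (``"sbml"``)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    return _read_tsv(path) if fmt == "tsv" else _read_sbml(path)


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write a model; the TSV dialect adds a ``.json`` metadata sidecar."""
    model.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        _write_tsv(model, path)
    else:
        _write_sbml(model, path)
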