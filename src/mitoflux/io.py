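"""Reading and writing metabolic models.

Three dialects are supported:

* ``native-json`` — this package's own schema (lossless round trip),
* ``sbml`` — SBML Level 3 with the FBC package, via python-libsbml,
* ``tabular`` — a spreadsheet/TSV layout common to COBRA supplementary
  tables: one row per reaction with columns {reaction id, name, formula
  string, lower bound, upper bound, gene rule, subsystem}, reaction
  formula strings written as ``"coef met_id + ... --> ..."`` with
  ``-->`` (irreversible) or ``<=>`` (reversible) arrows.

Foreign compartment tags: an inter-membrane-space tag ``i`` is mapped to
the cytosolic compartment ``c`` on load, matching the convention that
the outer membrane is freely permeable.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .core import (
    COMPARTMENTS,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

FORMATS = ("native-json", "sbml", "tabular")

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed under the named dialect."""


# ---------------------------------------------------------------- native json


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective": model.objective_reaction,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
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
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
    }


def _model_from_dict(doc: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gene_rule=r.get("gene_rule", ""),
                subsystem=r.get("subsystem", ""),
            )
            for r in doc["reactions"]
        ]
    except KeyError as exc:
        raise ModelParseError(f"native-json document missing key {exc}") from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_reaction=doc.get("objective"),
        id=doc.get("id", "model"),
    )


# ---------------------------------------------------------------------- sbml


def _sbml_sid(raw: str, prefix: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "__", raw)
    return prefix + sid


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_sid(model.id, ""))
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for comp in COMPARTMENTS:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sbml_sid(met.id, "M_"))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp_fbc = sp.getPlugin("fbc")
        if met.formula is not None:
            sp_fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp_fbc.setCharge(int(met.charge))

    # distinct bound values as shared parameters, per FBC convention
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gp.setId(_sbml_sid(gene, "G_"))
        gp.setLabel(gene)

    for rxn in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(_sbml_sid(rxn.id, "R_"))
        rx.setName(rxn.name or rxn.id)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sbml_sid(met_id, "M_"))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rx_fbc = rx.getPlugin("fbc")
        rx_fbc.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rx_fbc.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.gene_rule:
            gpa = rx_fbc.createGeneProductAssociation()
            infix = re.sub(
                r"\b(?!and\b|or\b)([A-Za-z0-9_.-]+)",
                lambda m: _sbml_sid(m.group(1), "G_"),
                rxn.gene_rule,
            )
            gpa.setAssociation(infix)

    if model.objective_reaction is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_sid(model.objective_reaction, "R_"))
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no model element in SBML document")

    def _map_comp(comp: str) -> str:
        comp = {"i": "c"}.get(comp, comp)
        if comp not in COMPARTMENTS:
            raise ModelValidationError(f"unknown compartment tag {comp!r} in {path}")
        return comp

    met_id_map: dict[str, str] = {}
    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = _map_comp(sp.getCompartment())
        raw = _strip_prefix(sp.getId(), "M_")
        if raw.endswith("_i"):
            raw = raw[:-2] + "_c"
        if not raw.endswith(f"_{comp}"):
            raw = f"{raw}_{comp}"
        met_id_map[sp.getId()] = raw
        sp_fbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sp_fbc is not None:
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula()
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
        mets.append(
            Metabolite(id=raw, name=sp.getName(), compartment=comp,
                       formula=formula, charge=charge)
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    gene_labels = {}
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = met_id_map[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = met_id_map[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        rx_fbc = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gene_rule = ""
        if rx_fbc is not None:
            if rx_fbc.isSetLowerFluxBound():
                lb = params[rx_fbc.getLowerFluxBound()]
            if rx_fbc.isSetUpperFluxBound():
                ub = params[rx_fbc.getUpperFluxBound()]
            gpa = rx_fbc.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                infix = gpa.getAssociation().toInfix()
                for gid, label in gene_labels.items():
                    infix = re.sub(rf"\b{re.escape(gid)}\b", label, infix)
                gene_rule = infix
        rxns.append(
            Reaction(
                id=_strip_prefix(rx.getId(), "R_"),
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
            )
        )

    objective = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        active = fbc.getActiveObjective()
        if active.getNumFluxObjectives() > 0:
            objective = _strip_prefix(active.getFluxObjective(0).getReaction(), "R_")

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_reaction=objective,
        id=sbml_model.getId() or "model",
    )


# -------------------------------------------------------------------- tabular


def parse_reaction_string(formula: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 a_c + b_c --> c_c"`` into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in formula), None)
    if arrow is None:
        raise ModelParseError(f"no reaction arrow in formula {formula!r}")
    reversible = arrow in ("<=>", "<->")
    lhs, rhs = formula.split(arrow, 1)

    def _side(text: str, sign: float, stoich: dict[str, float]) -> None:
        text = text.strip()
        if not text:
            return
        for term in re.split(r"\s\+\s|(?<=\s)\+(?=\s)", text):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelParseError(
                        f"bad coefficient {parts[0]!r} in term {term!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ModelParseError(f"cannot parse term {term!r}")
            if met.endswith("_i"):
                met = met[:-2] + "_c"
            stoich[met] = stoich.get(met, 0.0) + sign * coef
        return

    stoich: dict[str, float] = {}
    _side(lhs, -1.0, stoich)
    _side(rhs, +1.0, stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    if not stoich:
        raise ModelParseError(f"empty reaction formula {formula!r}")
    return stoich, reversible


_TABULAR_COLUMNS = {
    "reaction id": "id",
    "reaction": "formula",
    "id": "id",
    "abbreviation": "id",
    "name": "name",
    "description": "name",
    "formula": "formula",
    "reaction formula": "formula",
    "equation": "formula",
    "lower bound": "lower_bound",
    "lb": "lower_bound",
    "upper bound": "upper_bound",
    "ub": "upper_bound",
    "gene rule": "gene_rule",
    "gpr": "gene_rule",
    "gene association": "gene_rule",
    "subsystem": "subsystem",
}


def _read_tabular(path: Path, objective: str | None = None) -> MetabolicModel:
    import pandas as pd

    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path, sep="\t")
    rename = {}
    for col in table.columns:
        key = str(col).strip().lower()
        if key in _TABULAR_COLUMNS:
            rename[col] = _TABULAR_COLUMNS[key]
    table = table.rename(columns=rename)
    for required in ("id", "formula"):
        if required not in table.columns:
            raise ModelParseError(
                f"{path}: tabular model lacks a '{required}' column "
                f"(found {list(table.columns)})"
            )

    met_ids: dict[str, None] = {}
    rxns = []
    for record, row in enumerate(table.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            stoich, reversible = parse_reaction_string(str(row["formula"]))
        except ModelParseError as exc:
            raise ModelParseError(f"{path} record {record}: {exc}") from exc
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        lb = (-1000.0 if reversible else 0.0) if lb is None or pd.isna(lb) else float(lb)
        ub = 1000.0 if ub is None or pd.isna(ub) else float(ub)
        gene_rule = row.get("gene_rule")
        gene_rule = "" if gene_rule is None or pd.isna(gene_rule) else str(gene_rule)
        subsystem = row.get("subsystem")
        subsystem = "" if subsystem is None or pd.isna(subsystem) else str(subsystem)
        name = row.get("name")
        name = "" if name is None or pd.isna(name) else str(name)
        met_ids.update(dict.fromkeys(stoich))
        rxns.append(
            Reaction(
                id=str(row["id"]).strip(),
                name=name,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
                subsystem=subsystem,
            )
        )

    mets = []
    for met_id in met_ids:
        tag = met_id.rsplit("_", 1)[-1]
        if tag not in COMPARTMENTS:
            raise ModelValidationError(
                f"{path}: metabolite {met_id!r} has unknown compartment tag {tag!r}"
            )
        mets.append(Metabolite(id=met_id, compartment=tag))
    return MetabolicModel(
        metabolites=mets, reactions=rxns, objective_reaction=objective, id=path.stem
    )


# ------------------------------------------------------------------ frontend


def load_model(path: str | Path, format: str = "native-json") -> MetabolicModel:
    """Load a model from ``path`` in the named dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path} line {exc.lineno}: {exc.msg}") from exc
        return _model_from_dict(doc)
    if format == "sbml":
        return _read_sbml(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown model format {format!r} (expected one of {FORMATS})")


def save_model(model: MetabolicModel, path: str | Path, format: str = "native-json") -> None:
    """Write a model to ``path`` in the named dialect."""
    path = Path(path)
    if format == "native-json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif format == "sbml":
        _write_sbml(model, path)
    elif format == "tabular":
        save_reaction_table(model, path)
    else:
        raise ValueError(f"unknown model format {format!r} (expected one of {FORMATS})")


def reaction_to_string(rxn: Reaction) -> str:
    """Render a reaction as an arrow string (inverse of parse_reaction_string)."""
    def _fmt(met: str, coef: float) -> str:
        coef = abs(coef)
        return met if coef == 1 else f"{coef:g} {met}"

    lhs = " + ".join(_fmt(m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    rhs = " + ".join(_fmt(m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()


def save_reaction_table(model: MetabolicModel, path: str | Path) -> None:
    """Write the human-readable reaction TSV (tabular dialect)."""
    import pandas as pd

    rows = [
        {
            "reaction id": r.id,
            "name": r.name,
            "formula": reaction_to_string(r),
            "lower bound": r.lower_bound,
            "upper bound": r.upper_bound,
            "gene rule": r.gene_rule,
            "subsystem": r.subsystem,
        }
        for r in model.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
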