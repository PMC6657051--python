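"""Readers and writers for metabolic models.

Two on-disk dialects are supported: COBRA-style JSON (read and written
natively, and interoperable with ``cobra.io.load_json_model``) and SBML
Level 3 + FBC (delegated to cobrapy / libSBML).  Reaction kinds that the
formats do not encode (exchange, demand, biomass, orphan) are recovered
heuristically on read: boundary reactions by prefix and single-metabolite
stoichiometry, the biomass reaction from the objective coefficient, orphans
from an empty gene rule.
"""

from __future__ import annotations

import json
import logging
import pathlib

from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelError,
    ModelPatch,
    Reaction,
)

logger = logging.getLogger("emoma")


def _classify(rxn: Reaction, objective: bool) -> str:
    if objective:
        return "biomass"
    if len(rxn.stoichiometry) == 1:
        if rxn.id.startswith("DM_") or rxn.id.startswith("SK_"):
            return "demand"
        return "exchange"
    if rxn.is_orphan:
        return "orphan"
    return "internal"


# ---------------------------------------------------------------------------
# COBRA-dialect JSON
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    mets = []
    for m in model.metabolites:
        d: dict = {"id": m.id, "name": m.name, "compartment": m.compartment}
        if m.formula is not None:
            d["formula"] = m.formula
        if m.charge is not None:
            d["charge"] = m.charge
        mets.append(d)
    rxns = []
    for r in model.reactions:
        d = {
            "id": r.id,
            "name": r.name,
            "metabolites": dict(r.stoichiometry),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gene_reaction_rule": r.gene_rule or "",
            "objective_coefficient": 1.0 if r.kind == "biomass" else 0.0,
            "kind": r.kind,
        }
        rxns.append(d)
    return {"id": model.id, "metabolites": mets, "reactions": rxns, "genes": []}


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        met_items = data["metabolites"]
        rxn_items = data["reactions"]
    except KeyError as exc:
        raise ModelError(f"malformed model JSON: missing key {exc}") from exc
    model = MetabolicModel(id=data.get("id", "model"))
    for m in met_items:
        try:
            model.metabolites.append(Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula") or None,
                charge=m.get("charge"),
            ))
        except KeyError as exc:
            raise ModelError(f"malformed metabolite entry {m!r}: missing {exc}") from exc
    any_objective = False
    for r in rxn_items:
        try:
            stoich = {k: float(v) for k, v in r["metabolites"].items()}
        except KeyError as exc:
            raise ModelError(f"malformed reaction entry {r!r}: missing {exc}") from exc
        lb = r.get("lower_bound")
        ub = r.get("upper_bound")
        if lb is None or ub is None:
            # Community default: +/-1000 for reversible, [0, 1000] otherwise.
            rev = bool(r.get("reversible", False))
            lb = -DEFAULT_BOUND if rev and lb is None else (0.0 if lb is None else lb)
            ub = DEFAULT_BOUND if ub is None else ub
            logger.info(
                "reaction %s: missing bounds, defaulted to [%s, %s]", r["id"], lb, ub
            )
        rule = r.get("gene_reaction_rule", "") or None
        rxn = Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry=stoich,
            lower_bound=float(lb),
            upper_bound=float(ub),
            gene_rule=rule,
        )
        objective = float(r.get("objective_coefficient", 0.0)) != 0.0
        any_objective = any_objective or objective
        rxn.kind = r.get("kind") or _classify(rxn, objective)
        model.reactions.append(rxn)
    if not any_objective and not any(r.kind == "biomass" for r in model.reactions):
        raise ModelError("no objective defined in model file")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# cobra interop
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a ``cobra.Model`` (used for SBML output and as a bridge)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment,
            formula=m.formula, charge=m.charge,
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        crxn = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if r.gene_rule:
            crxn.gene_reaction_rule = r.gene_rule
    cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a ``cobra.Model`` into a :class:`MetabolicModel`."""
    model = MetabolicModel(id=cm.id or "model")
    for m in cm.metabolites:
        model.metabolites.append(Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "c",
            formula=m.formula or None,
            charge=int(m.charge) if m.charge is not None else None,
        ))
    objective_ids = {
        r.id for r in cm.reactions
        if getattr(r, "objective_coefficient", 0.0)
    }
    if not objective_ids:
        raise ModelError("no objective defined in model file")
    for r in cm.reactions:
        rxn = Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(v) for m, v in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gene_rule=r.gene_reaction_rule or None,
        )
        rxn.kind = _classify(rxn, r.id in objective_ids)
        model.reactions.append(rxn)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _sniff_format(path: pathlib.Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    head = path.read_bytes()[:200].lstrip()
    return "sbml" if head.startswith(b"<") else "json"


def read_model(path, format: str = "auto") -> MetabolicModel:
    """Read a metabolic model from SBML (L3+FBC) or COBRA-dialect JSON.

    Raises :class:`ModelError` for malformed files, inverted bounds or a
    missing objective (never a silently zero objective).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelError(f"malformed JSON in {path}: {exc}") from exc
        return _model_from_dict(data)
    if format == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:
            raise ModelError(f"cannot parse SBML {path}: {exc}") from exc
        return from_cobra(cm)
    raise ValueError(f"unknown format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "auto") -> None:
    """Write a model to JSON or SBML such that :func:`read_model` round-trips."""
    model.validate()
    path = pathlib.Path(path)
    if format == "auto":
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_patch(path) -> ModelPatch:
    """Load a :class:`ModelPatch` from a JSON list of edit objects."""
    data = json.loads(pathlib.Path(path).read_text())
    if not isinstance(data, list):
        raise ModelError("patch file must contain a JSON list of edits")
    return ModelPatch.from_dicts(data)
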